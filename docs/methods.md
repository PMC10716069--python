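# Methods

## Measures and scoring

**Pointing error.** Each trial records a response bearing and a true bearing,
both clockwise degrees in [0, 360) from the imagined facing direction. The
trial score is the folded circular difference `min(|Δ| mod 360, 360 − |Δ| mod
360)` in [0°, 180°]; the participant score is the arithmetic mean over trials,
reported separately for Phase I (before shortcutting) and Phase II (after).
Uniform responding has an exactly uniform folded error, hence an expected
score of 90° — the chance floor every inference against "better than chance"
uses. `true_bearing` converts planar coordinates (observer, facing point,
target) into the correct bearing for simulation and end-to-end checks.

**Travel efficiency.** Per trial, traveled length divided by the shortest
traversable path length between the same start and goal on the maze graph;
1 is optimal. Shortest paths are Dijkstra lengths on an undirected metric
graph (networkx); graph validity (positive edge lengths, connectivity,
landmarks on nodes, learned route along edges) is enforced at construction.
Failed (timed-out) trials carry no traveled length and are imputed with the
**learned-route efficiency**: the mean over trial pairs of the along-tour
distance divided by the shortest-path distance. The along-tour distance walks
the learned route forward from the start landmark, wrapping past the end only
when the route is closed (first node = last node); on an open route a target
behind the start is an error rather than a silent backward walk. The two
emulated environments fix this constant at 2.54 and 2.19; both are accepted
as configuration overrides when no maze is supplied.

**Exclusions.** Participants failing *strictly more than* 30% of shortcut
trials are removed from both measures; afterwards any trial whose failure
fraction among remaining participants is *at least* 30% is removed. The
asymmetric thresholds are deliberate: the participant rule is worded as
"more than", while the one excluded trial in the emulated study sat exactly
at the 30% boundary, so the trial rule must be inclusive. A tolerance of
1e−12 keeps fractions that are exactly on a threshold from being pushed over
it by floating-point rounding. Every removal is logged with its fraction.

## Permutation split-half reliability

For a participants × trials matrix, one split partitions the columns into
halves (sizes differing by at most one; for odd counts the larger half falls
on either side with probability 1/2), computes each participant's half-means
(ignoring missing cells; a participant with no observation in a half is
dropped for that split), correlates the half-means across participants, and
applies the Spearman–Brown correction `2r/(1+r)`. The estimate is the
arithmetic mean of the corrected correlation over `n_permutations = 5000`
uniformly random partitions (the default follows the common convention of the
permutation-based estimator; the count, like the aggregation rule, is
configurable). Individual split correlations are not clamped and neither is
the mean: a value outside [0, 1] is reported with an `out_of_range` flag,
because with little true between-person variance the estimator legitimately
goes negative and hiding that would mask exactly the pathology the analysis
is about. The permutation distribution (SD, 2.5/97.5 percentiles) is kept for
uncertainty summaries. The implementation evaluates all partitions in one
vectorized pass (masked matrix products), so 5,000 permutations on a
57 × 27 matrix take milliseconds. Estimation needs at least 2 columns and
warns below 5 rows / 4 columns.

## Correlations, disattenuation and inference

Correlations are Pearson throughout (the t/df inference format of the
emulated analyses matches Pearson inference). For observed `r` with `n`
participants: `t = r·sqrt((n−2)/(1−r²))` on `n−2` df, two-sided p, and a 95%
CI from `tanh(atanh(r) ± z/sqrt(n−3))`.

Disattenuation divides the observed correlation by `sqrt(r_xx·r_yy)`.
Sampling noise in either the correlation or the reliabilities can push the
corrected value past 1; it is returned unclamped with a flag and only shrunk
to ±0.999 inside Fisher-z machinery that needs `|r| < 1`. When a group's
reliability estimate is non-positive the correction is undefined; the
pipeline then reports the observed correlation alone and logs the fallback.

Two independent correlations are compared with the Fisher-z statistic
`(atanh r₁ − atanh r₂)/sqrt(1/(n₁−3) + 1/(n₂−3))` and Zou's 95% CI for
`r₁ − r₂`, assembled from the individual Fisher-z CIs. The pipeline applies
the comparison to disattenuated values when both groups have them (their
sampling distribution is approximated as if they were plain correlations — a
documented caveat of the approach), falling back to observed correlations
otherwise.

Power for detecting a population correlation ρ uses the Fisher-z normal
approximation `Φ(sqrt(n−3)·atanh ρ − z_{1−α/2})` plus the negligible opposite
tail; tests cross-check it against Monte-Carlo rejection rates of the exact
t test (agreement within 0.02 at n = 48, ρ = 0.4).

## Ability clustering and group inference

K-means runs on the three measures (efficiency, Phase I and II pointing
error), z-scored per measure because they live on incommensurate scales —
this also makes the assignment invariant to per-measure affine rescaling.
Each candidate k in 2…6 is fit with 50 random initializations and a fixed
seed (bit-reproducible); the chosen k maximizes the mean silhouette, with the
inertia curve reported for elbow inspection rather than automated (the two
criteria have no principled arbitration rule). With k = 2 the cluster with
lower mean Phase I pointing error is labeled "high" (ties broken by
efficiency); larger k merges clusters by comparing cluster means to the grand
mean.

Group descriptives report mean, SD (n−1), min, max, adjusted Fisher–Pearson
skewness and *excess* kurtosis (both sample-bias-corrected; conventions are
stated because the emulated tables leave them implicit), trial count, and the
group's own permutation split-half reliability (omitted with a warning below
5 participants, reported NaN for degenerate matrices).

One-sample t tests (`t = (mean − μ₀)/(sd/√n)`, df = n−1, Cohen's
`d = (mean − μ₀)/sd`, t-based CI of the mean) accept either raw values or
printed summary statistics; the two entry points agree to 12 decimals, which
is what lets published tables be replayed exactly without raw data
(`replay_printed`, `confignav replay-printed`, packaged summaries in
`data/published/printed_summaries.csv`).

## Synthetic cohorts

The generator reproduces the *statistical* structure the analysis assumes,
not any cognitive process. A cohort mixes two latent clusters; each
participant draws a (pointing, shortcutting) ability pair from a per-cluster
bivariate normal with correlation ρ (default 0.95 within clusters).

*Pointing*: with probability `g(a) = expit(g₀ − g₁a)` a response is uniform
on [0, 360) (the guessing floor); otherwise the signed error is von Mises
with concentration `exp(κ₀ + κ₁a − b_j)`, where `b_j ~ N(0, 0.4)` is a
per-trial difficulty offset. The von Mises family is one of several wrapped
unimodal choices that admit the uniform limit; nothing downstream depends on
the specific family.

*Shortcutting*: success is Bernoulli with logit `s₀ + s₁a − b_j`; successful
trials score exactly 1 with probability `expit(c₀ + c₁a)` (the ceiling mass)
or `1 + excess` with gamma-distributed excess whose scale is
`exp(e₀ − e₁a + b_j)`, censored above at the learned-route efficiency.
Trial pairs and shortest-path denominators come from a synthetic stand-in
maze (`fixture_maze`: a square grid with 12 landmark nodes and a closed
boundary tour — the real maze geometries are not machine-readable and only
these structural features matter downstream). `simulate_walk` additionally
provides noisy greedy trajectories for end-to-end exercise of the efficiency
scorer.

The two presets encode the emulated study conditions: **desktop-like**
(57 participants, 20 high / 37 low, 27 pointing trials per phase, 20 shortcut
trials, imputation constant 2.54) and **immersive-like** (48 participants,
24/24, 24 + 24 trials, constant 2.19, less guessing, stronger ceiling).
Response-model coefficients were calibrated once, empirically (simulate,
measure, adjust the gain), so that the desktop-like cohort lands near the
emulated study's moments: whole-sample Phase I pointing ≈ 74° (SD ≈ 23) with
split-half reliability ≈ 0.83 at 27 trials, efficiency ≈ 1.8, a low cluster
pointing in the 80–95° band with reliability well below 0.5, and a high
cluster around 50° with reliability ≈ 0.8. Closed forms for the split-half
reliability of these mixture models are unavailable, so calibration is
empirical by design. All randomness flows from one root seed through named
substreams (cohort, difficulty, pointing I/II, shortcut, walks), so stages
are independently reproducible and identical seeds give byte-identical CSVs.

`generate_attenuation_study` is a deliberately minimal Gaussian counterpart
for measurement-theory checks: per-trial score = ability + noise with noise
variance `J(1−R)/R`, making the J-trial mean's reliability exactly R and the
population correlation of observed means exactly `ρ·sqrt(R_x·R_y)` — the
attenuation law the correction inverts.

**What passing tests do and do not show.** The generator has exchangeable
trials within difficulty, no learning or fatigue across trials, no response
biases (e.g., axis alignment), independent trials given ability, and
efficiencies hard-censored at the imputation constant, whereas real
participants can travel farther than the learned route. Recovery results
therefore validate the estimators under the classical-test-theory structure
they assume, not the behavioral realism of any particular study.

## Problem sizes and numerical choices

The attenuation-recovery study uses 200 cohorts of n = 60 with 300
permutations per reliability estimate (the permutation mean is unbiased for
the expected split-half correlation, so fewer permutations add variance, not
bias, and the 200-cohort average absorbs it). The dissociation check uses
medians over five replicate desktop-like cohorts with 500 permutations: at
n = 20 per high cluster a single cohort's correlation has sampling SD ≈ 0.13,
and the median damps that noise without touching the generative conditions.
Efficiency ratio checks allow 1e−9 relative slack for float summation;
exclusion fractions get 1e−12 absolute slack at thresholds. K-means and all
simulations are seeded; permutation estimators are reproducible given
(seed, n_permutations).

## Known limitations

- Disattenuated values routinely exceed 1 when reliabilities are small; they
  are flagged, and inference on them (Fisher-z comparison) treats them as
  plain correlations — an approximation, not a sampling theory for the
  corrected estimator. Bootstrap CIs for disattenuated correlations are out
  of scope.
- Only independent-groups correlation comparisons are provided; overlapping-
  sample (dependent) comparisons are not.
- Reliability here is internal consistency only — no test–retest, no
  Cronbach's alpha, no ICC.
- The maze model is planar and single-floor; trajectory analysis beyond
  total length (shape, pausing, heading) is out of scope.
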