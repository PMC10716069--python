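# confignav

Psychometric analysis of **configural spatial knowledge** — the integrated,
map-like mental representation that lets a navigator infer directions and
shortcuts between places never experienced together. The package scores the
two standard behavioral measures of that knowledge, quantifies how trustworthy
each measure is, and corrects the correlation between them for measurement
error:

- **Pointing error** (judgments of relative direction): a participant imagines
  standing at one landmark facing another and indicates the direction to a
  third. The trial score is the absolute angular disparity between response
  and truth, in degrees on [0°, 180°]; directionally uninformative responding
  averages 90° (chance).
- **Travel efficiency** (route-based shortcutting): the distance traveled to a
  goal divided by the shortest traversable path length, so 1 is optimal.
  Unsuccessful (timed-out) trials are imputed with the *learned-route
  efficiency* — the ratio a participant would score by always retracing the
  guided tour (2.54 and 2.19 for the two study environments the defaults
  emulate).
- **Internal consistency** by permutation split-half: the trials are split at
  random into halves, the half-means are correlated across participants, the
  Spearman–Brown prophecy `2r/(1+r)` steps the correlation up to full test
  length, and the estimate is the mean over 5,000 random splits.
- **Correction for attenuation**: with reliabilities `r_xx`, `r_yy`, the
  correlation between the underlying abilities is estimated as

  ```
  r_disattenuated = r_observed / sqrt(r_xx * r_yy)
  ```

- **Ability clustering and group inference**: k-means on the z-scored measures
  (k chosen by silhouette, inertia curve reported for elbow inspection) splits
  a cohort into high- and low-spatial groups; per-group descriptives,
  reliabilities, correlations, Fisher-z comparison of two independent
  correlations with Zou's 95% CI for the difference, one-sample t tests
  against chance pointing and against the learned-route efficiency, and the
  Fisher-z power approximation for detecting a population correlation.

Because raw human data are not bundled, a first-class **synthetic cohort
generator** provides ground truth for every stage: two latent ability
clusters with correlated pointing/shortcutting abilities, a guessing + von
Mises mixture for pointing (producing the 90° chance floor), and an
ability-dependent censored-gamma efficiency model with a point mass at the
perfect score (producing the ceiling at 1).

Intended users: researchers in spatial cognition and individual differences
who need reliability-aware scoring of navigation tasks, and methodologists
who want a worked, testable example of attenuation correction on floor/
ceiling-limited measures.

## Worked example

```python
from confignav import (preset, generate_study, analyze_study, RunConfig)

cfg = preset("desktop-like", seed=1)          # 57 simulants, 27 + 27 + 20 trials
bundle = generate_study(cfg)
report = analyze_study(
    bundle["pointing"], bundle["shortcut"],
    RunConfig(learned_route_eff=2.54, n_permutations=5000, seed=1),
)
print(report.correlation_matrix.round(2))
print(report.assignment.chosen_k)
lo = report.group_correlations["low"]; hi = report.group_correlations["high"]
print(f"low r = {lo.r_observed:.2f} (p = {lo.p:.2f}), high r = {hi.r_observed:.2f}")
```

prints (observed correlations below the diagonal, disattenuated above):

```
                   efficiency  pointing_error_I  pointing_error_II
efficiency                NaN              1.01               0.98
pointing_error_I         0.88               NaN               1.02
pointing_error_II        0.86              0.88                NaN
2
low r = 0.21 (p = 0.21), high r = 0.69
```

Read: the whole-cohort measures correlate strongly and the correction for
attenuation pushes the estimates to (and slightly past — flagged, never
silently clamped) 1. Silhouette picks two ability clusters. Within the
low-ability cluster, pointing sits near the 90° chance floor with near-zero
internal consistency, so its correlation with shortcutting is indistinguishable
from zero, while the high-ability cluster shows a substantial correlation —
the dissociation the cohort was built to exhibit.

The same pipeline is available as numbered analysis drivers
(`analysis/01_simulate.py` … `analysis/06_replay_printed.py`, writing tables
under `results/`) and as a CLI:

```sh
confignav simulate --preset desktop-like --seed 1 --out results/data/desktop
confignav analyze --pointing-1 ... --pointing-2 ... --shortcut ... --out results/report
confignav replay-printed
```

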