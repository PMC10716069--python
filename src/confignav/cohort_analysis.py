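"""Ability clustering, group descriptives and one-sample inference.

Participants are split into high- and low-spatial-ability groups by
k-means on three z-scored measures (travel efficiency, Phase I and
Phase II pointing error). The number of clusters is chosen by the mean
silhouette over a candidate range, with the inertia (elbow) curve
reported alongside for inspection. The cluster with the higher mean
Phase I pointing error is labeled "low".

Per-group descriptives mirror a standard psychometrics summary: mean,
SD, min, max, adjusted Fisher-Pearson skewness, excess kurtosis, trial
count, and permutation split-half internal consistency.

One-sample t tests compare a group mean against a reference value —
chance-level pointing (90 deg) or the learned-route efficiency — and
accept either raw values or printed summary statistics (mean, SD, n),
so published tables can be replayed without raw data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .reliability import permutation_split_half

__all__ = [
    "GroupAssignment",
    "OneSampleResult",
    "cluster_participants",
    "group_descriptives",
    "one_sample_test",
]

CLUSTER_FEATURES = ["efficiency", "pointing_error_I", "pointing_error_II"]


@dataclass(frozen=True)
class GroupAssignment:
    """high/low labels with the k-selection diagnostics that produced them."""

    labels: pd.Series  # participant_id -> "high" | "low"
    chosen_k: int
    inertia: dict[int, float]
    silhouette: dict[int, float]
    seed: int | None
    cluster_ids: pd.Series = field(default=None)  # raw k-means cluster per participant

    def group(self, name: str) -> pd.Index:
        return self.labels.index[self.labels == name]


@dataclass(frozen=True)
class OneSampleResult:
    """One-sample t test of a mean against a reference value mu0."""

    t: float
    df: int
    p: float
    cohen_d: float
    ci95: tuple[float, float]
    mu0: float
    n: int
    mean: float
    sd: float


def cluster_participants(
    scores: pd.DataFrame,
    k_candidates=range(2, 7),
    seed: int | None = 0,
    n_init: int = 50,
) -> GroupAssignment:
    """k-means ability clustering on z-scored measures, silhouette-selected k.

    Requires all of ``efficiency``, ``pointing_error_I`` and
    ``pointing_error_II``; participants missing any are dropped from
    clustering. The chosen k maximizes the mean silhouette; the inertia
    curve over candidates is reported for elbow inspection. When the
    chosen k exceeds 2, the high/low split merges clusters by comparing
    each cluster's mean Phase I pointing error to the grand mean; with
    k = 2 the lower-error cluster is "high" (ties broken by efficiency).
    """
    feats = scores[CLUSTER_FEATURES].dropna()
    k_candidates = list(k_candidates)
    if len(feats) < max(k_candidates):
        raise ValueError(
            f"{len(feats)} participants with complete measures; need >= {max(k_candidates)}"
        )
    X = (feats - feats.mean()) / feats.std(ddof=1)
    X = X.to_numpy()

    inertia: dict[int, float] = {}
    sil: dict[int, float] = {}
    fits: dict[int, np.ndarray] = {}
    for k in k_candidates:
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
        lab = km.fit_predict(X)
        inertia[k] = float(km.inertia_)
        sil[k] = float(silhouette_score(X, lab)) if len(set(lab)) > 1 else float("nan")
        fits[k] = lab
    chosen_k = max(sil, key=lambda k: sil[k])
    lab = fits[chosen_k]

    cluster_ids = pd.Series(lab, index=feats.index, name="cluster")
    err = feats["pointing_error_I"].groupby(cluster_ids).mean()
    eff = feats["efficiency"].groupby(cluster_ids).mean()
    if chosen_k == 2:
        order = sorted(err.index, key=lambda c: (err[c], eff[c]))
        name_of = {order[0]: "high", order[1]: "low"}
    else:
        grand = feats["pointing_error_I"].mean()
        name_of = {c: ("high" if err[c] <= grand else "low") for c in err.index}
    labels = cluster_ids.map(name_of)
    labels.name = "group"
    return GroupAssignment(
        labels=labels, chosen_k=chosen_k, inertia=inertia, silhouette=sil,
        seed=seed, cluster_ids=cluster_ids,
    )


def _descriptive_row(values: np.ndarray) -> dict:
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    row = {
        "n": int(values.size),
        "mean": float(values.mean()),
        "sd": float(values.std(ddof=1)) if values.size > 1 else float("nan"),
        "min": float(values.min()),
        "max": float(values.max()),
    }
    if row["sd"] and row["sd"] > 0:
        row["skewness"] = float(stats.skew(values, bias=False))
        row["kurtosis"] = float(stats.kurtosis(values, bias=False))  # excess
    else:
        row["skewness"] = float("nan")
        row["kurtosis"] = float("nan")
    return row


def group_descriptives(
    scores: pd.DataFrame,
    trial_matrices: dict[str, pd.DataFrame],
    assignment: GroupAssignment | None = None,
    n_permutations: int = 5000,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Per-measure (optionally per-group) descriptives + internal consistency.

    ``trial_matrices`` maps measure name -> wide participants x trials
    matrix on the measure's per-trial scale; reliability is the
    permutation split-half estimate on the group's rows. Groups smaller
    than 5 get no reliability (warning).
    """
    groups: dict[str, pd.Index]
    if assignment is None:
        groups = {"all": scores.index}
    else:
        groups = {name: assignment.group(name) for name in ("high", "low")}
    rows = []
    for gname, idx in groups.items():
        if len(idx) == 0:
            raise ValueError(f"group {gname!r} is empty")
        for measure, matrix in trial_matrices.items():
            vals = scores.loc[scores.index.intersection(idx), measure].dropna()
            row = {"group": gname, "measure": measure, **_descriptive_row(vals.to_numpy())}
            sub = matrix.loc[matrix.index.intersection(idx)]
            row["n_trials"] = int(sub.shape[1])
            if len(sub) < 5:
                warnings.warn(
                    f"group {gname!r} has {len(sub)} participants; reliability omitted",
                    stacklevel=2,
                )
                row["reliability"] = float("nan")
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    try:
                        row["reliability"] = permutation_split_half(
                            sub, n_permutations=n_permutations, seed=seed, measure=measure
                        ).estimate
                    except ValueError:  # degenerate (e.g. constant) matrix
                        row["reliability"] = float("nan")
            rows.append(row)
    return pd.DataFrame(rows)


def one_sample_test(
    values=None, mu0: float = 0.0, *, mean: float | None = None,
    sd: float | None = None, n: int | None = None, alpha: float = 0.05,
) -> OneSampleResult:
    """One-sample t test against ``mu0``, from raw values or summary stats.

    ``t = (mean - mu0) / (sd / sqrt(n))``, df = n - 1, two-sided p,
    Cohen's d = (mean - mu0) / sd, and the t-based 95% CI of the mean.
    The summary entry point (``mean=, sd=, n=``) exists so printed
    tables can be replayed exactly.
    """
    if values is not None:
        values = np.asarray(values, dtype=float)
        values = values[np.isfinite(values)]
        n = int(values.size)
        if n < 2:
            raise ValueError("need n >= 2")
        mean = float(values.mean())
        sd = float(values.std(ddof=1))
    else:
        if mean is None or sd is None or n is None:
            raise ValueError("supply raw values or all of mean, sd, n")
        if n < 2:
            raise ValueError("need n >= 2")
    if not sd > 0:
        raise ValueError("sd must be positive")
    df = n - 1
    se = sd / np.sqrt(n)
    t = (mean - mu0) / se
    p = 2.0 * stats.t.sf(abs(t), df)
    d = (mean - mu0) / sd
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
    ci = (mean - tcrit * se, mean + tcrit * se)
    return OneSampleResult(
        t=float(t), df=df, p=float(p), cohen_d=float(d),
        ci95=(float(ci[0]), float(ci[1])), mu0=float(mu0), n=n,
        mean=float(mean), sd=float(sd),
    )
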