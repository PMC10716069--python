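"""Permutation split-half internal consistency with Spearman-Brown correction.

Internal consistency asks whether a participant's score on one random
half of the trials predicts their score on the other half. A single
split gives the Pearson correlation, across participants, between the
two half-means; the Spearman-Brown prophecy ``2r / (1 + r)`` steps that
half-length correlation up to the full test length. Because any one
split is arbitrary, the permutation estimator averages the corrected
correlation over many uniformly random half-partitions of the trial
columns, which also yields a permutation distribution for uncertainty
summaries.

Estimates are *not* clamped: a noisy measure can produce a negative or
slightly > 1 mean, and hiding that would mask estimator pathology. The
estimate carries an ``out_of_range`` flag instead.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ReliabilityEstimate",
    "spearman_brown",
    "split_half_once",
    "permutation_split_half",
]

MIN_ROWS = 5
MIN_COLS = 4


@dataclass(frozen=True)
class ReliabilityEstimate:
    """Permutation split-half internal consistency for one measure."""

    measure: str
    estimate: float
    n_permutations: int
    n_participants: int
    n_trials: int
    dist_mean: float
    dist_sd: float
    dist_p2_5: float
    dist_p97_5: float
    seed: int | None
    out_of_range: bool

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(asdict(self), indent=1)
        if path is not None:
            Path(path).write_text(payload)
        return payload


def spearman_brown(r_half: float) -> float:
    """Step a split-half correlation up to full test length: 2r / (1 + r)."""
    if r_half == -1:
        raise ValueError("Spearman-Brown is undefined at r_half = -1")
    return 2.0 * r_half / (1.0 + r_half)


def _as_matrix(matrix) -> np.ndarray:
    if isinstance(matrix, pd.DataFrame):
        return matrix.to_numpy(dtype=float)
    return np.asarray(matrix, dtype=float)


def _half_corr(values: np.ndarray, masks_a: np.ndarray, masks_b: np.ndarray) -> np.ndarray:
    """Pearson r between half-means for a batch of column partitions.

    ``values`` is participants x trials (NaN = missing). ``masks_a`` and
    ``masks_b`` are n_perm x trials boolean column-membership masks.
    Missing cells are ignored within each half (pairwise-complete rows);
    a participant with no observed cell in either half is dropped for
    that split. Returns one correlation per partition.
    """
    obs = np.isfinite(values)
    filled = np.where(obs, values, 0.0)
    obs_f = obs.astype(float)  # bool @ bool is logical, not a count
    ma_f, mb_f = masks_a.T.astype(float), masks_b.T.astype(float)

    # per-split half means: rows x perms
    sums_a = filled @ ma_f
    cnts_a = obs_f @ ma_f
    sums_b = filled @ mb_f
    cnts_b = obs_f @ mb_f
    valid = (cnts_a > 0) & (cnts_b > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ma = np.where(valid, sums_a / np.maximum(cnts_a, 1), np.nan)
        mb = np.where(valid, sums_b / np.maximum(cnts_b, 1), np.nan)

    n = valid.sum(axis=0).astype(float)
    w = valid.astype(float)
    xa = np.where(valid, ma, 0.0)
    xb = np.where(valid, mb, 0.0)
    mean_a = xa.sum(axis=0) / n
    mean_b = xb.sum(axis=0) / n
    da = (xa - mean_a) * w
    db = (xb - mean_b) * w
    cov = (da * db).sum(axis=0)
    va = (da * da).sum(axis=0)
    vb = (db * db).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = cov / np.sqrt(va * vb)
    return r


def split_half_once(matrix, half_a, half_b) -> float:
    """Spearman-Brown-corrected correlation for one explicit column partition.

    ``half_a`` / ``half_b`` index columns (positions for an array,
    labels for a DataFrame); they must disjointly cover all columns with
    sizes differing by at most 1.
    """
    if isinstance(matrix, pd.DataFrame):
        cols = list(matrix.columns)
        ia = np.array([cols.index(c) for c in half_a])
        ib = np.array([cols.index(c) for c in half_b])
    else:
        ia = np.asarray(half_a, dtype=int)
        ib = np.asarray(half_b, dtype=int)
    values = _as_matrix(matrix)
    n_cols = values.shape[1]
    if set(ia) & set(ib) or len(ia) + len(ib) != n_cols or len(set(ia) | set(ib)) != n_cols:
        raise ValueError("halves must disjointly cover all columns")
    if abs(len(ia) - len(ib)) > 1:
        raise ValueError("half sizes may differ by at most 1")
    mask_a = np.zeros((1, n_cols), dtype=bool)
    mask_b = np.zeros((1, n_cols), dtype=bool)
    mask_a[0, ia] = True
    mask_b[0, ib] = True
    r = float(_half_corr(values, mask_a, mask_b)[0])
    return spearman_brown(r)


def permutation_split_half(
    matrix,
    n_permutations: int = 5000,
    seed: int | None = None,
    measure: str = "measure",
    rng: np.random.Generator | None = None,
) -> ReliabilityEstimate:
    """Mean Spearman-Brown split-half correlation over random partitions.

    Each permutation draws a uniformly random partition of the trial
    columns into halves (for odd column counts the larger half falls on
    either side with equal probability), correlates the two half-means
    across participants, applies the Spearman-Brown correction, and the
    estimate is the arithmetic mean over permutations.
    """
    values = _as_matrix(matrix)
    n_rows, n_cols = values.shape
    if n_cols < 2:
        raise ValueError("need at least 2 trial columns")
    if n_cols < MIN_COLS or n_rows < MIN_ROWS:
        warnings.warn(
            f"matrix is {n_rows} x {n_cols}; estimates below "
            f"{MIN_ROWS} rows / {MIN_COLS} columns are unstable",
            stacklevel=2,
        )
    if n_permutations < 1:
        raise ValueError("n_permutations must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)

    # random partitions: argsort of uniforms gives a random column order;
    # the first k columns form half A. For odd n_cols, k is n_cols//2 or
    # n_cols//2 + 1 with equal probability.
    order = np.argsort(rng.random((n_permutations, n_cols)), axis=1)
    k = np.full(n_permutations, n_cols // 2)
    if n_cols % 2:
        k = k + rng.integers(0, 2, size=n_permutations)
    ranks = np.empty_like(order)
    np.put_along_axis(ranks, order, np.arange(n_cols)[None, :].repeat(n_permutations, 0), axis=1)
    masks_a = ranks < k[:, None]
    masks_b = ~masks_a

    r = _half_corr(values, masks_a, masks_b)
    corrected = 2.0 * r / (1.0 + r)
    finite = corrected[np.isfinite(corrected)]
    if finite.size == 0:
        raise ValueError("no finite split correlations (degenerate matrix)")
    est = float(finite.mean())
    out_of_range = not (0.0 <= est <= 1.0)
    if out_of_range:
        warnings.warn(f"reliability estimate {est:.3f} outside [0, 1]", stacklevel=2)
    return ReliabilityEstimate(
        measure=measure,
        estimate=est,
        n_permutations=n_permutations,
        n_participants=n_rows,
        n_trials=n_cols,
        dist_mean=float(finite.mean()),
        dist_sd=float(finite.std(ddof=1)) if finite.size > 1 else 0.0,
        dist_p2_5=float(np.percentile(finite, 2.5)),
        dist_p97_5=float(np.percentile(finite, 97.5)),
        seed=seed,
        out_of_range=out_of_range,
    )
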