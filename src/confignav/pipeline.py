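"""End-to-end study analysis: exclusions -> imputation -> scoring ->
reliability -> correlations -> clustering -> group inference.

This is the programmatic core behind the ``confignav analyze`` command
and the analysis drivers: one function that takes the two raw trial
tables (and the study configuration) and returns every table the study
report needs, as plain pandas/dataclass objects.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import association, cohort_analysis, trial_scoring
from .reliability import permutation_split_half

__all__ = ["RunConfig", "StudyReport", "analyze_study", "replay_printed"]

MEASURES = ["efficiency", "pointing_error_I", "pointing_error_II"]
CHANCE_POINTING_DEG = 90.0


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one analysis run."""

    learned_route_eff: float = 2.54
    participant_fail_max: float = 0.30
    trial_fail_max: float = 0.30
    n_permutations: int = 5000
    seed: int = 0
    matching_pairs_only: bool = False

    def __post_init__(self):
        for name in ("participant_fail_max", "trial_fail_max"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if not self.learned_route_eff > 1:
            raise ValueError("learned_route_eff must exceed 1")


@dataclass
class StudyReport:
    """Everything ``analyze_study`` computes, ready for serialization."""

    scores: pd.DataFrame
    reliabilities: dict
    correlation_matrix: pd.DataFrame
    correlation_reports: list
    assignment: object  # GroupAssignment | None
    group_descriptives: pd.DataFrame | None
    group_correlations: dict
    group_comparison: object  # CorrelationComparison | None
    one_sample_tests: dict
    exclusion_log: object
    run_config: RunConfig
    messages: list[str]


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in asdict(obj).items()}
    if isinstance(obj, pd.DataFrame):
        return json.loads(obj.to_json(orient="split"))
    if isinstance(obj, pd.Series):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    if obj is None or isinstance(obj, (str, int, float, bool)):
        return obj
    return str(obj)


def report_to_json(report: StudyReport) -> str:
    payload = {
        "scores": _jsonable(report.scores.reset_index()),
        "reliabilities": _jsonable(report.reliabilities),
        "correlation_matrix": _jsonable(report.correlation_matrix),
        "correlation_reports": _jsonable(report.correlation_reports),
        "assignment": None
        if report.assignment is None
        else {
            "labels": _jsonable(report.assignment.labels),
            "chosen_k": report.assignment.chosen_k,
            "inertia": _jsonable(report.assignment.inertia),
            "silhouette": _jsonable(report.assignment.silhouette),
            "seed": report.assignment.seed,
        },
        "group_descriptives": _jsonable(report.group_descriptives),
        "group_correlations": _jsonable(report.group_correlations),
        "group_comparison": _jsonable(report.group_comparison),
        "one_sample_tests": _jsonable(report.one_sample_tests),
        "exclusions": {
            "participants": _jsonable(report.exclusion_log.participants),
            "trials": _jsonable(report.exclusion_log.trials),
        },
        "run_config": _jsonable(report.run_config),
        "messages": report.messages,
    }
    return json.dumps(payload, indent=1)


def analyze_study(
    pointing: pd.DataFrame, shortcut: pd.DataFrame, config: RunConfig = RunConfig()
) -> StudyReport:
    """Run the full analysis pipeline on raw trial tables.

    Steps: exclusion rules; imputation of failed shortcut trials with the
    learned-route efficiency; participant scoring; permutation split-half
    reliability per measure; observed + disattenuated correlation matrix;
    k-means high/low clustering with per-group descriptives, correlations
    and a Fisher-z comparison of the disattenuated pointing-efficiency
    correlations; one-sample tests against chance pointing (90 deg) and
    against the learned-route efficiency, whole-sample and per group.

    Clustering and group inference degrade gracefully: if too few
    participants carry all three measures, those sections are None and a
    message is logged, but everything upstream is still returned.
    """
    messages: list[str] = []
    pointing, shortcut, log = trial_scoring.apply_exclusions(
        pointing, shortcut, config.participant_fail_max, config.trial_fail_max
    )
    messages.extend(log.summary().splitlines() if (log.participants or log.trials) else [])

    eff_trials = trial_scoring.impute_failed(shortcut, config.learned_route_eff)
    scores = trial_scoring.score_participants(
        pointing, eff_trials, matching_pairs_only=config.matching_pairs_only
    )

    matrices = {
        "pointing_error_I": trial_scoring.pointing_trial_matrix(pointing, "I"),
        "pointing_error_II": trial_scoring.pointing_trial_matrix(pointing, "II"),
        "efficiency": trial_scoring.efficiency_trial_matrix(eff_trials),
    }
    matrices = {m: mat for m, mat in matrices.items() if mat.size}

    reliabilities = {}
    for measure, mat in matrices.items():
        try:
            est = permutation_split_half(
                mat, n_permutations=config.n_permutations, seed=config.seed, measure=measure
            )
        except ValueError as exc:
            messages.append(f"reliability of {measure} unavailable: {exc}")
            continue
        reliabilities[measure] = est
        if est.out_of_range:
            messages.append(f"reliability of {measure} outside [0, 1]: {est.estimate:.3f}")

    rel_values = {m: est.estimate for m, est in reliabilities.items()}
    present = [m for m in MEASURES if m in scores.columns and m in rel_values]
    corr_matrix = association.correlation_matrix_table(scores, rel_values, present)
    corr_reports = []
    for i, mi in enumerate(present):
        for mj in present[i + 1 :]:
            sub = scores[[mi, mj]].dropna()
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                rep = association.correlation_report(
                    sub[mi], sub[mj], rel_values[mi], rel_values[mj], mi, mj
                )
            for w in caught:
                messages.append(f"{mi} vs {mj}: {w.message}")
            corr_reports.append(rep)

    assignment = None
    group_desc = None
    group_corr: dict = {}
    comparison = None
    one_sample: dict = {}

    if all(m in scores.columns for m in MEASURES):
        complete = scores[MEASURES].dropna()
        try:
            assignment = cohort_analysis.cluster_participants(scores, seed=config.seed)
        except ValueError as exc:
            messages.append(f"clustering skipped: {exc}")

    for label, idx in [("all", scores.index)] + (
        [(g, assignment.group(g)) for g in ("high", "low")] if assignment is not None else []
    ):
        sub = scores.loc[scores.index.intersection(idx)]
        if "pointing_error_I" in sub:
            vals = sub["pointing_error_I"].dropna()
            if len(vals) >= 2 and vals.std(ddof=1) > 0:
                one_sample[f"{label}_pointing_I_vs_chance"] = cohort_analysis.one_sample_test(
                    vals, CHANCE_POINTING_DEG
                )
        if "efficiency" in sub:
            vals = sub["efficiency"].dropna()
            if len(vals) >= 2 and vals.std(ddof=1) > 0:
                one_sample[f"{label}_efficiency_vs_learned_route"] = cohort_analysis.one_sample_test(
                    vals, config.learned_route_eff
                )

    if assignment is not None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            group_desc = cohort_analysis.group_descriptives(
                scores, matrices, assignment,
                n_permutations=config.n_permutations, seed=config.seed,
            )
        for gname in ("high", "low"):
            idx = assignment.group(gname)
            sub = scores.loc[scores.index.intersection(idx), MEASURES].dropna()
            gd = group_desc[group_desc["group"] == gname].set_index("measure")["reliability"]
            if len(sub) < 4 or sub["pointing_error_I"].std() == 0 or sub["efficiency"].std() == 0:
                messages.append(f"group {gname}: too few/degenerate scores for correlation")
                continue
            rxx = float(gd.get("pointing_error_I", np.nan))
            ryy = float(gd.get("efficiency", np.nan))
            usable = np.isfinite(rxx) and np.isfinite(ryy) and rxx > 0 and ryy > 0
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                if usable:
                    rep = association.correlation_report(
                        sub["pointing_error_I"], sub["efficiency"], rxx, ryy,
                        "pointing_error_I", "efficiency",
                    )
                else:
                    # a non-positive reliability estimate makes the correction
                    # undefined; report the observed correlation alone
                    messages.append(
                        f"group {gname}: non-positive reliability, disattenuation skipped"
                    )
                    r = association.pearson_r(sub["pointing_error_I"], sub["efficiency"])
                    t, df_, p, ci = association.correlation_test(r, len(sub))
                    rep = association.CorrelationReport(
                        measure_x="pointing_error_I", measure_y="efficiency",
                        r_observed=r, n=len(sub), t=t, df=df_, p=p, ci95=ci,
                        r_xx=rxx, r_yy=ryy, r_disattenuated=float("nan"),
                        disattenuated_out_of_range=False,
                    )
            group_corr[gname] = rep
        if {"high", "low"} <= set(group_corr):
            hi, lo = group_corr["high"], group_corr["low"]
            # compare disattenuated values when both exist, observed otherwise
            if np.isfinite(lo.r_disattenuated) and np.isfinite(hi.r_disattenuated):
                r_lo, r_hi = lo.r_disattenuated, hi.r_disattenuated
            else:
                r_lo, r_hi = lo.r_observed, hi.r_observed
                messages.append("group comparison uses observed correlations")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                comparison = association.compare_correlations(
                    r_lo, lo.n, r_hi, hi.n, label_1="low", label_2="high",
                )

    return StudyReport(
        scores=scores,
        reliabilities=reliabilities,
        correlation_matrix=corr_matrix,
        correlation_reports=corr_reports,
        assignment=assignment,
        group_descriptives=group_desc,
        group_correlations=group_corr,
        group_comparison=comparison,
        one_sample_tests=one_sample,
        exclusion_log=log,
        run_config=config,
        messages=messages,
    )


def replay_printed(rows: pd.DataFrame) -> pd.DataFrame:
    """Recompute inferential statistics from printed summary rows.

    ``rows`` carries a ``kind`` column with two row types:

    * ``one_sample``: columns label, mean, sd, n, mu0 -> t, df, p,
      cohen_d, ci95.
    * ``disattenuate``: columns label, r_obs, r_xx, r_yy ->
      r_disattenuated.

    This drives the replay of published tables without raw data.
    """
    out = []
    for pos, row in enumerate(rows.itertuples(index=False)):
        d = row._asdict()
        kind = d.get("kind")
        try:
            if kind == "one_sample":
                res = cohort_analysis.one_sample_test(
                    mean=float(d["mean"]), sd=float(d["sd"]), n=int(d["n"]), mu0=float(d["mu0"])
                )
                out.append(
                    {
                        "label": d["label"], "kind": kind, "t": res.t, "df": res.df,
                        "p": res.p, "cohen_d": res.cohen_d,
                        "ci95_lo": res.ci95[0], "ci95_hi": res.ci95[1],
                    }
                )
            elif kind == "disattenuate":
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    value, flag = association.disattenuate(
                        float(d["r_obs"]), float(d["r_xx"]), float(d["r_yy"])
                    )
                out.append(
                    {
                        "label": d["label"], "kind": kind,
                        "r_disattenuated": value, "out_of_range": flag,
                    }
                )
            else:
                raise ValueError(f"unknown kind {kind!r}")
        except (KeyError, TypeError, ValueError) as exc:
            raise ValueError(f"malformed row {pos}: {exc}") from exc
    return pd.DataFrame(out)


def load_printed_summaries() -> pd.DataFrame:
    """The packaged published-table summary rows (means, SDs, printed r's)."""
    path = Path(__file__).parent / "data" / "published" / "printed_summaries.csv"
    return pd.read_csv(path)
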