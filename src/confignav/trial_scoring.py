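"""Trial-level scoring: pointing error and travel efficiency.

Turns raw trial records into the two participant-level measures of
configural spatial knowledge:

* **Pointing Error** — the absolute angular disparity, in degrees on
  [0, 180], between the indicated and the true direction from one
  landmark while facing another, averaged over trials and reported per
  task phase (Phase I before the shortcutting task, Phase II after).
  Directionally uninformative (uniform) responding yields 90 deg on
  average, the chance level.
* **Travel Efficiency** — the ratio of the distance traveled to the
  shortest traversable path on each shortcutting trial (1 = optimal),
  averaged over trials. Unsuccessful (timed-out) trials are imputed
  with the learned-route efficiency: the efficiency a participant would
  score by always retracing the guided tour.

Exclusion rules: participants who fail *more than* a threshold fraction
of shortcut trials (default 30%) are removed from both measures; after
that, any trial whose failure fraction reaches the trial threshold
(default 30%, inclusive) is removed for everyone.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "POINTING_COLUMNS",
    "SHORTCUT_COLUMNS",
    "absolute_angular_error",
    "true_bearing",
    "apply_exclusions",
    "impute_failed",
    "score_participants",
    "ExclusionLog",
]

POINTING_COLUMNS = [
    "participant_id",
    "phase",
    "trial_id",
    "start_landmark",
    "target_landmark",
    "response_bearing_deg",
    "true_bearing_deg",
]

SHORTCUT_COLUMNS = [
    "participant_id",
    "trial_id",
    "start_landmark",
    "target_landmark",
    "success",
    "traveled_length_m",
    "shortest_length_m",
]

#: Relative slack for the ``efficiency >= 1`` invariant (float summation).
EFFICIENCY_TOL = 1e-9


def absolute_angular_error(response_bearing_deg, true_bearing_deg):
    """Absolute circular difference in degrees, on [0, 180].

    Accepts scalars or arrays. The raw difference is reduced modulo 360
    and folded onto the half-circle: ``min(|d|, 360 - |d|)``.
    """
    d = np.abs(np.asarray(response_bearing_deg, dtype=float) - np.asarray(true_bearing_deg, dtype=float)) % 360.0
    out = np.minimum(d, 360.0 - d)
    return float(out) if out.ndim == 0 else out


def true_bearing(observer, facing_point, target) -> float:
    """Clockwise angle in degrees [0, 360) from observer->facing to observer->target.

    This is the correct pointer-circle response for a participant
    standing at ``observer``, facing ``facing_point``, pointing to
    ``target``.
    """
    ox, oy = observer
    fvec = (facing_point[0] - ox, facing_point[1] - oy)
    tvec = (target[0] - ox, target[1] - oy)
    for name, v in (("facing_point", fvec), ("target", tvec)):
        if math.hypot(*v) == 0.0:
            raise ValueError(f"{name} coincides with the observer (zero-length ray)")
    # counter-clockwise angle of each ray, then clockwise difference
    ang = math.degrees(math.atan2(tvec[1], tvec[0]) - math.atan2(fvec[1], fvec[0]))
    return (-ang) % 360.0


@dataclass
class ExclusionLog:
    """Record of every removal made by :func:`apply_exclusions`."""

    participants: list[tuple[str, float]] = field(default_factory=list)  # (id, fail fraction)
    trials: list[tuple[object, float]] = field(default_factory=list)  # (trial_id, fail fraction)

    def summary(self) -> str:
        lines = [
            f"participant {pid} removed (failed {frac:.0%} of shortcut trials)"
            for pid, frac in self.participants
        ] + [
            f"trial {tid} removed ({frac:.0%} of remaining participants failed)"
            for tid, frac in self.trials
        ]
        return "\n".join(lines) if lines else "no exclusions"


def apply_exclusions(
    pointing: pd.DataFrame,
    shortcut: pd.DataFrame,
    participant_fail_max: float = 0.30,
    trial_fail_max: float = 0.30,
) -> tuple[pd.DataFrame, pd.DataFrame, ExclusionLog]:
    """Apply participant- then trial-level exclusions.

    Participants whose shortcut failure fraction strictly exceeds
    ``participant_fail_max`` are dropped from both tables. Then any
    shortcut trial whose failure fraction among the remaining
    participants is >= ``trial_fail_max`` is dropped. Returns the
    filtered copies and an :class:`ExclusionLog`.
    """
    log = ExclusionLog()
    sc = shortcut.copy()
    pt = pointing.copy()

    # small slack so a fraction sitting exactly on the threshold is not
    # pushed over it by floating-point rounding
    eps = 1e-12
    fail_frac = 1.0 - sc.groupby("participant_id")["success"].mean()
    bad = fail_frac[fail_frac > participant_fail_max + eps]
    for pid, frac in bad.items():
        log.participants.append((pid, float(frac)))
    if len(bad):
        sc = sc[~sc["participant_id"].isin(bad.index)]
        pt = pt[~pt["participant_id"].isin(bad.index)]

    trial_fail = 1.0 - sc.groupby("trial_id")["success"].mean()
    bad_trials = trial_fail[trial_fail >= trial_fail_max - eps]
    for tid, frac in bad_trials.items():
        log.trials.append((tid, float(frac)))
    if len(bad_trials):
        sc = sc[~sc["trial_id"].isin(bad_trials.index)]

    if sc.empty or pt.empty:
        raise ValueError("all data removed by exclusion rules")
    return pt.reset_index(drop=True), sc.reset_index(drop=True), log


def impute_failed(shortcut: pd.DataFrame, learned_route_eff: float) -> pd.DataFrame:
    """Per-trial efficiency with failed trials imputed.

    Successful trials carry ``traveled_length_m / shortest_length_m``;
    unsuccessful trials carry ``learned_route_eff`` (the mean efficiency
    of always retracing the learned route).
    """
    if not learned_route_eff > 1:
        raise ValueError(f"learned_route_eff must exceed 1, got {learned_route_eff}")
    if shortcut["shortest_length_m"].isna().any():
        raise ValueError("missing shortest_length_m")
    out = shortcut.copy()
    success = out["success"].astype(bool)
    if out.loc[success, "traveled_length_m"].isna().any():
        raise ValueError("successful trial with missing traveled_length_m")
    ratio = out["traveled_length_m"] / out["shortest_length_m"]
    out["efficiency"] = np.where(success, ratio, learned_route_eff)
    bad = out["efficiency"] < 1.0 - EFFICIENCY_TOL * np.maximum(1.0, out["efficiency"].abs())
    if bad.any():
        row = out[bad].iloc[0]
        raise ValueError(
            f"trial {row['trial_id']} of participant {row['participant_id']} has efficiency "
            f"{row['efficiency']:.6f} < 1; traveled shorter than the shortest path"
        )
    return out


def score_participants(
    pointing: pd.DataFrame | None,
    efficiency_trials: pd.DataFrame | None,
    matching_pairs_only: bool = False,
) -> pd.DataFrame:
    """Participant-level scores: mean pointing error per phase, mean efficiency.

    Returns a frame indexed by ``participant_id`` with columns
    ``pointing_error_I``, ``pointing_error_II``, ``efficiency`` and the
    matching trial counts (``n_pointing_I``, ``n_pointing_II``,
    ``n_shortcut``). Participants present for only one measure are
    scored on what exists, with a warning.

    With ``matching_pairs_only`` the pointing table is restricted to
    (start, target) landmark pairs that also occur in the shortcutting
    table, mirroring the corresponding-trials sensitivity analysis.
    """
    frames = []
    if pointing is not None and len(pointing):
        pt = pointing
        if matching_pairs_only:
            if efficiency_trials is None or not {"start_landmark", "target_landmark"} <= set(
                efficiency_trials.columns
            ):
                raise ValueError("matching_pairs_only requires shortcut landmark pairs")
            pairs = set(
                zip(efficiency_trials["start_landmark"], efficiency_trials["target_landmark"])
            ) | set(
                zip(efficiency_trials["target_landmark"], efficiency_trials["start_landmark"])
            )
            keep = [
                (s, t) in pairs
                for s, t in zip(pt["start_landmark"], pt["target_landmark"])
            ]
            pt = pt[np.asarray(keep)]
        err = absolute_angular_error(
            pt["response_bearing_deg"].to_numpy(), pt["true_bearing_deg"].to_numpy()
        )
        pt = pt.assign(error=err)
        for phase, label in (("I", "pointing_error_I"), ("II", "pointing_error_II")):
            sub = pt[pt["phase"] == phase]
            if len(sub):
                g = sub.groupby("participant_id")["error"]
                frames.append(pd.DataFrame({label: g.mean(), f"n_pointing_{phase}": g.size()}))
    if efficiency_trials is not None and len(efficiency_trials):
        if "efficiency" not in efficiency_trials.columns:
            raise ValueError("efficiency_trials must carry an 'efficiency' column (run impute_failed)")
        g = efficiency_trials.groupby("participant_id")["efficiency"]
        frames.append(pd.DataFrame({"efficiency": g.mean(), "n_shortcut": g.size()}))
    if not frames:
        raise ValueError("no trials to score")
    scores = pd.concat(frames, axis=1)
    scores.index.name = "participant_id"
    value_cols = [c for c in ("pointing_error_I", "pointing_error_II", "efficiency") if c in scores]
    missing = scores[value_cols].isna().any(axis=1)
    if missing.any():
        warnings.warn(
            f"{int(missing.sum())} participant(s) missing at least one measure; "
            "scored on available measures only",
            stacklevel=2,
        )
    return scores


def pointing_trial_matrix(pointing: pd.DataFrame, phase: str) -> pd.DataFrame:
    """Wide participants x trials matrix of absolute pointing errors."""
    sub = pointing[pointing["phase"] == phase].copy()
    sub["error"] = absolute_angular_error(
        sub["response_bearing_deg"].to_numpy(), sub["true_bearing_deg"].to_numpy()
    )
    return sub.pivot_table(index="participant_id", columns="trial_id", values="error")


def efficiency_trial_matrix(efficiency_trials: pd.DataFrame) -> pd.DataFrame:
    """Wide participants x trials matrix of per-trial efficiency ratios."""
    return efficiency_trials.pivot_table(
        index="participant_id", columns="trial_id", values="efficiency"
    )
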