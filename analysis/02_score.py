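"""Apply exclusion rules, impute failed trials, and score participants.

Reads the raw trial tables written by 01_simulate.py, drops participants
failing more than 30% of shortcut trials and trials failed by at least
30% of the remaining participants, replaces unsuccessful trials with the
learned-route efficiency, and writes participant-level scores.
"""

from pathlib import Path

import pandas as pd

from confignav.trial_scoring import apply_exclusions, impute_failed, score_participants

ROOT = Path(__file__).resolve().parent.parent / "results"
LEARNED_ROUTE_EFF = {"desktop": 2.54, "immersive": 2.19}


def main() -> None:
    tables = ROOT / "tables"
    tables.mkdir(parents=True, exist_ok=True)
    for study, lre in LEARNED_ROUTE_EFF.items():
        data = ROOT / "data" / study
        pointing = pd.concat(
            [pd.read_csv(data / "pointing_phase_I.csv"), pd.read_csv(data / "pointing_phase_II.csv")],
            ignore_index=True,
        )
        shortcut = pd.read_csv(data / "shortcut.csv")
        pointing, shortcut, log = apply_exclusions(pointing, shortcut)
        print(f"{study}: exclusions -> {log.summary()}")
        eff = impute_failed(shortcut, lre)
        scores = score_participants(pointing, eff)
        scores.to_csv(tables / f"scores_{study}.csv")
        eff.to_csv(ROOT / "data" / study / "efficiency_trials.csv", index=False)
        print(
            f"{study}: {len(scores)} participants | pointing I "
            f"{scores['pointing_error_I'].mean():.1f} deg (SD {scores['pointing_error_I'].std():.1f}) | "
            f"efficiency {scores['efficiency'].mean():.2f} (SD {scores['efficiency'].std():.2f})"
        )


if __name__ == "__main__":
    main()
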