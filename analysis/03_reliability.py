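"""Permutation split-half internal consistency of each measure.

For each study, builds the participants x trials matrix of each measure
(pointing error per phase, per-trial efficiency after imputation) and
estimates its Spearman-Brown-corrected split-half reliability over 5,000
random partitions.
"""

from pathlib import Path

import pandas as pd

from confignav.reliability import permutation_split_half
from confignav.trial_scoring import (
    apply_exclusions,
    efficiency_trial_matrix,
    pointing_trial_matrix,
)

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 1


def main() -> None:
    rows = []
    for study in ("desktop", "immersive"):
        data = ROOT / "data" / study
        pointing = pd.concat(
            [pd.read_csv(data / "pointing_phase_I.csv"), pd.read_csv(data / "pointing_phase_II.csv")],
            ignore_index=True,
        )
        eff = pd.read_csv(data / "efficiency_trials.csv")
        pointing = pointing[pointing["participant_id"].isin(eff["participant_id"])]
        matrices = {
            "pointing_error_I": pointing_trial_matrix(pointing, "I"),
            "pointing_error_II": pointing_trial_matrix(pointing, "II"),
            "efficiency": efficiency_trial_matrix(eff),
        }
        for measure, mat in matrices.items():
            est = permutation_split_half(mat, n_permutations=5000, seed=SEED, measure=measure)
            rows.append(
                {
                    "study": study,
                    "measure": measure,
                    "reliability": est.estimate,
                    "n_trials": est.n_trials,
                    "n_participants": est.n_participants,
                    "perm_sd": est.dist_sd,
                }
            )
            print(f"{study} {measure}: reliability {est.estimate:.2f} ({est.n_trials} trials)")
    out = ROOT / "tables" / "reliability.csv"
    pd.DataFrame(rows).to_csv(out, index=False)
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
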