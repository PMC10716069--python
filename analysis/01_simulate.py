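"""Generate the two synthetic study datasets.

Writes a desktop-like cohort (57 simulants: 20 high-, 37 low-spatial;
27 pointing trials per phase, 20 shortcut trials, learned-route
efficiency 2.54) and an immersive-like cohort (48 simulants: 24 + 24;
24 + 24 trials, learned-route efficiency 2.19) under results/data/.
"""

from pathlib import Path

from confignav.synthetic_cohort import generate_study, preset

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "results" / "data"


def main() -> None:
    for name in ("desktop-like", "immersive-like"):
        cfg = preset(name, seed=SEED)
        out_dir = OUT / name.replace("-like", "")
        bundle = generate_study(cfg, out_dir=out_dir)
        n = bundle["cohort"].table.shape[0]
        n_point = bundle["pointing"].shape[0]
        n_short = bundle["shortcut"].shape[0]
        print(
            f"{name}: {n} simulants, {n_point} pointing trials, "
            f"{n_short} shortcut trials -> {out_dir}"
        )
    print(f"done (seed {SEED})")


if __name__ == "__main__":
    main()
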