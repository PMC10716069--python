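import numpy as np
import pandas as pd
import pytest

from confignav.maze_paths import shortest_path_length
from confignav.synthetic_cohort import (
    ClusterSpec,
    SimConfig,
    fixture_maze,
    generate_cohort,
    generate_pointing_trials,
    generate_shortcut_trials,
    generate_study,
    preset,
    simulate_walk,
)
from confignav.trial_scoring import absolute_angular_error, impute_failed, score_participants


def one_cluster_config(n=100, **overrides) -> SimConfig:
    base = dict(
        clusters={"only": ClusterSpec(n=n, pointing_mean=0.0, pointing_sd=1.0,
                                      shortcut_mean=0.0, shortcut_sd=1.0, rho=0.5)},
        n_pointing_trials=10,
        n_shortcut_trials=8,
        seed=99,
    )
    base.update(overrides)
    return SimConfig(**base)


class TestGenerateCohort:
    def test_determinism(self):
        cfg = one_cluster_config()
        a = generate_cohort(cfg).table
        b = generate_cohort(cfg).table
        pd.testing.assert_frame_equal(a, b)

    def test_rho_one_affinely_identical(self):
        cfg = one_cluster_config(
            clusters={"c": ClusterSpec(n=200, pointing_mean=1.0, pointing_sd=2.0,
                                       shortcut_mean=-1.0, shortcut_sd=0.5, rho=1.0)}
        )
        t = generate_cohort(cfg).table
        z1 = (t["pointing_ability"] - 1.0) / 2.0
        z2 = (t["shortcut_ability"] + 1.0) / 0.5
        assert np.allclose(z1, z2, atol=1e-8)

    def test_sample_correlation_converges(self):
        cfg = one_cluster_config(
            n=5000,
            clusters={"c": ClusterSpec(n=5000, pointing_mean=0, pointing_sd=1,
                                       shortcut_mean=0, shortcut_sd=1, rho=0.75)},
        )
        t = generate_cohort(cfg).table
        r = np.corrcoef(t["pointing_ability"], t["shortcut_ability"])[0, 1]
        assert r == pytest.approx(0.75, abs=0.03)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(clusters={"c": ClusterSpec(n=0, pointing_mean=0, pointing_sd=1,
                                                 shortcut_mean=0, shortcut_sd=1, rho=0)})
        with pytest.raises(ValueError, match="rho"):
            ClusterSpec(n=5, pointing_mean=0, pointing_sd=1,
                        shortcut_mean=0, shortcut_sd=1, rho=1.5)


class TestGeneratePointingTrials:
    def test_pure_guessing_means_near_chance(self):
        """With the guessing probability pinned at 1, every participant's
        mean error sits near the analytic 90 deg chance level."""
        cfg = one_cluster_config(n=60, guess_intercept=50.0, guess_slope=0.0,
                                 n_pointing_trials=400)
        cohort = generate_cohort(cfg)
        trials = generate_pointing_trials(cohort, cfg, "I")
        scores = score_participants(trials, None)
        errs = scores["pointing_error_I"]
        # per-participant SE of the mean of 400 uniform absolute errors
        se = np.sqrt(2700.0 / 400)
        assert ((errs - 90.0).abs() < 4 * se).mean() > 0.95
        assert errs.mean() == pytest.approx(90.0, abs=3 * se / np.sqrt(60))

    def test_degenerate_precision_zero_error(self):
        cfg = one_cluster_config(n=20, guess_intercept=-50.0, guess_slope=0.0,
                                 kappa_intercept=20.0, kappa_gain=0.0,
                                 pointing_difficulty_sd=1e-9)
        cohort = generate_cohort(cfg)
        trials = generate_pointing_trials(cohort, cfg, "I")
        err = absolute_angular_error(
            trials["response_bearing_deg"].to_numpy(), trials["true_bearing_deg"].to_numpy()
        )
        assert err.max() < 0.5

    def test_bearings_in_range_and_schema(self):
        cfg = one_cluster_config()
        trials = generate_pointing_trials(generate_cohort(cfg), cfg, "II")
        assert trials["phase"].eq("II").all()
        for col in ("response_bearing_deg", "true_bearing_deg"):
            assert trials[col].between(0, 360, inclusive="left").all()


class TestGenerateShortcutTrials:
    def test_high_ability_limit_perfect(self):
        cfg = one_cluster_config(
            clusters={"c": ClusterSpec(n=30, pointing_mean=0, pointing_sd=1,
                                       shortcut_mean=50.0, shortcut_sd=1e-6, rho=0.0)}
        )
        trials = generate_shortcut_trials(generate_cohort(cfg), cfg)
        assert trials["success"].all()
        eff = trials["traveled_length_m"] / trials["shortest_length_m"]
        assert eff.max() == pytest.approx(1.0)

    def test_low_ability_limit_fails_and_imputes_to_ceiling(self):
        cfg = one_cluster_config(
            clusters={"c": ClusterSpec(n=30, pointing_mean=0, pointing_sd=1,
                                       shortcut_mean=-50.0, shortcut_sd=1e-6, rho=0.0)}
        )
        trials = generate_shortcut_trials(generate_cohort(cfg), cfg)
        assert not trials["success"].any()
        imputed = impute_failed(trials, cfg.learned_route_eff)
        assert (imputed["efficiency"] == cfg.learned_route_eff).all()

    def test_invariants_fuzz(self):
        """Generated values always satisfy downstream invariants: efficiency
        >= 1 and bounded by the ceiling, boolean success, positive lengths."""
        cfg = one_cluster_config(n=500, n_shortcut_trials=20)
        trials = generate_shortcut_trials(generate_cohort(cfg), cfg)
        assert len(trials) == 10_000
        assert trials["success"].isin([True, False]).all()
        assert (trials["shortest_length_m"] > 0).all()
        ok = trials["success"]
        eff = trials.loc[ok, "traveled_length_m"] / trials.loc[ok, "shortest_length_m"]
        assert (eff >= 1 - 1e-9).all()
        assert (eff <= cfg.learned_route_eff + 1e-9).all()

    def test_ceiling_mass_depresses_reliability(self):
        """A configuration putting most successful trials exactly at 1
        yields lower split-half reliability than the same latent variance
        without the ceiling mass."""
        from confignav.reliability import permutation_split_half
        from confignav.trial_scoring import efficiency_trial_matrix

        common = dict(n=300, n_shortcut_trials=20, success_intercept=50.0)
        ceiling_cfg = one_cluster_config(**common, perfect_intercept=2.0, perfect_slope=0.0)
        open_cfg = one_cluster_config(**common, perfect_intercept=-50.0, perfect_slope=0.0)
        rels = {}
        for name, cfg in (("ceiling", ceiling_cfg), ("open", open_cfg)):
            trials = generate_shortcut_trials(generate_cohort(cfg), cfg)
            mat = efficiency_trial_matrix(impute_failed(trials, cfg.learned_route_eff))
            rels[name] = permutation_split_half(mat, 300, seed=0).estimate
        assert rels["ceiling"] < rels["open"]


class TestSimulateWalk:
    def test_full_fidelity_is_shortest_path(self):
        maze = fixture_maze()
        nodes = list(maze.nodes)
        traj, reached = simulate_walk(maze, nodes[0], nodes[-1], fidelity=1.0, seed=0)
        assert reached
        assert traj.total_length == pytest.approx(
            shortest_path_length(maze, nodes[0], nodes[-1])
        )

    def test_random_walk_longer_than_shortest(self):
        maze = fixture_maze()
        nodes = list(maze.nodes)
        start, goal = nodes[0], nodes[-1]
        shortest = shortest_path_length(maze, start, goal)
        lengths = []
        for seed in range(30):
            traj, reached = simulate_walk(maze, start, goal, fidelity=0.0,
                                          max_steps=500, seed=seed)
            if reached:
                lengths.append(traj.total_length)
        assert lengths and np.mean(lengths) > shortest

    def test_seed_determinism(self):
        maze = fixture_maze()
        a, _ = simulate_walk(maze, "n00", "n33", fidelity=0.5, seed=7)
        b, _ = simulate_walk(maze, "n00", "n33", fidelity=0.5, seed=7)
        assert a == b


class TestGenerateStudy:
    def test_bundle_schemas_and_files(self, tmp_path):
        cfg = preset("desktop-like", seed=5)
        bundle = generate_study(cfg, out_dir=tmp_path)
        for fname in ("pointing_phase_I.csv", "pointing_phase_II.csv",
                      "shortcut.csv", "maze.json", "sim_config.json"):
            assert (tmp_path / fname).exists()
        assert set(bundle["pointing"]["phase"]) == {"I", "II"}
        n = sum(c.n for c in cfg.clusters.values())
        assert bundle["shortcut"]["participant_id"].nunique() == n

    def test_same_seed_byte_identical(self, tmp_path):
        cfg = preset("desktop-like", seed=3)
        generate_study(cfg, out_dir=tmp_path / "a")
        generate_study(cfg, out_dir=tmp_path / "b")
        for f in ("pointing_phase_I.csv", "shortcut.csv", "maze.json"):
            assert (tmp_path / "a" / f).read_bytes() == (tmp_path / "b" / f).read_bytes()

    def test_different_seeds_distinct_same_schema(self):
        a = generate_study(preset("desktop-like", seed=1))
        b = generate_study(preset("desktop-like", seed=2))
        assert list(a["pointing"].columns) == list(b["pointing"].columns)
        assert not a["pointing"]["response_bearing_deg"].equals(
            b["pointing"]["response_bearing_deg"]
        )

    def test_low_group_points_near_chance(self):
        """The harder-study preset's low cluster has a mean pointing error in
        the 80-95 deg band around its near-chance calibration."""
        cfg = preset("desktop-like", seed=1)
        bundle = generate_study(cfg)
        scores = score_participants(
            bundle["pointing"], impute_failed(bundle["shortcut"], cfg.learned_route_eff)
        )
        truth = bundle["cohort"].table.set_index("participant_id")["cluster"]
        low_mean = scores.loc[truth[truth == "low"].index, "pointing_error_I"].mean()
        assert 80.0 <= low_mean <= 95.0

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError, match="unknown preset"):
            preset("tabletop")

    def test_config_json_round_trip(self, tmp_path):
        cfg = preset("immersive-like", seed=9)
        path = tmp_path / "cfg.json"
        cfg.to_json(path)
        again = SimConfig.from_json(path)
        assert again == cfg
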