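import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from confignav.trial_scoring import (
    absolute_angular_error,
    apply_exclusions,
    impute_failed,
    pointing_trial_matrix,
    score_participants,
    true_bearing,
)

finite_deg = st.floats(min_value=-1e6, max_value=1e6, allow_nan=False)


class TestAbsoluteAngularError:
    @pytest.mark.parametrize(
        "resp, true, expected",
        [(90, 90, 0), (350, 10, 20), (0, 180, 180), (10, 350, 20), (359.5, 0.5, 1.0)],
    )
    def test_examples(self, resp, true, expected):
        assert absolute_angular_error(resp, true) == pytest.approx(expected)

    @given(a=finite_deg, b=finite_deg, k=st.integers(-5, 5))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_symmetric_and_periodic(self, a, b, k):
        e = absolute_angular_error(a, b)
        assert 0 <= e <= 180
        assert e == pytest.approx(absolute_angular_error(b, a))
        assert e == pytest.approx(absolute_angular_error(a + 360 * k, b), abs=1e-6)

    def test_uniform_responses_average_90(self, rng):
        """Directionally uninformative responding scores 90 deg on average."""
        n = 200_000
        errs = absolute_angular_error(rng.uniform(0, 360, n), rng.uniform(0, 360, n))
        se = errs.std() / math.sqrt(n)
        assert abs(errs.mean() - 90.0) < 3 * se


class TestTrueBearing:
    @pytest.mark.parametrize(
        "facing, target, expected",
        [
            ((0, 1), (0, 2), 0.0),     # dead ahead
            ((0, 1), (1, 0), 90.0),    # due right
            ((0, 1), (1, -1), 135.0),  # behind-right
            ((0, 1), (1, 1), 45.0),    # ahead-right
            ((0, 1), (-1, 1), 315.0),  # ahead-left
            ((1, 0), (0, -1), 90.0),   # facing east, target south = clockwise 90
        ],
    )
    def test_known_configurations(self, facing, target, expected):
        assert true_bearing((0, 0), facing, target) == pytest.approx(expected)

    def test_zero_ray_raises(self):
        with pytest.raises(ValueError, match="zero-length"):
            true_bearing((1, 1), (1, 1), (2, 2))

    def test_rotation_matrix_oracle(self, rng):
        """Rotate the frame so the facing direction is north; the bearing is
        then the clockwise angle of the rotated target vector."""
        for _ in range(100):
            obs = rng.uniform(-5, 5, 2)
            facing = obs + rng.uniform(-3, 3, 2)
            target = obs + rng.uniform(-3, 3, 2)
            if np.allclose(facing, obs) or np.allclose(target, obs):
                continue
            f = facing - obs
            theta = math.atan2(f[1], f[0])  # rotate facing onto +y axis
            rot = math.pi / 2 - theta
            c, s = math.cos(rot), math.sin(rot)
            t = target - obs
            tx, ty = c * t[0] - s * t[1], s * t[0] + c * t[1]
            expected = math.degrees(math.atan2(tx, ty)) % 360.0
            got = true_bearing(tuple(obs), tuple(facing), tuple(target))
            assert got == pytest.approx(expected, abs=1e-9)


def _pointing_table(participants, n_trials=4):
    rows = []
    for pid in participants:
        for j in range(n_trials):
            rows.append(
                {
                    "participant_id": pid,
                    "phase": "I",
                    "trial_id": f"I-{j}",
                    "start_landmark": "a",
                    "target_landmark": "b",
                    "response_bearing_deg": 10.0,
                    "true_bearing_deg": 20.0,
                }
            )
    return pd.DataFrame(rows)


def _shortcut_table(success_by_participant):
    rows = []
    for pid, successes in success_by_participant.items():
        for j, s in enumerate(successes):
            rows.append(
                {
                    "participant_id": pid,
                    "trial_id": f"S-{j}",
                    "start_landmark": "a",
                    "target_landmark": "b",
                    "success": bool(s),
                    "traveled_length_m": 10.0 if s else np.nan,
                    "shortest_length_m": 5.0,
                }
            )
    return pd.DataFrame(rows)


class TestApplyExclusions:
    def test_participant_over_30pct_removed(self):
        succ = {f"p{i}": [True] * 10 for i in range(9)}
        succ["bad"] = [False] * 4 + [True] * 6  # 40% failures
        pt = _pointing_table(list(succ))
        p2, s2, log = apply_exclusions(pt, _shortcut_table(succ))
        assert "bad" not in set(s2["participant_id"])
        assert "bad" not in set(p2["participant_id"])
        assert log.participants == [("bad", pytest.approx(0.4))]

    def test_participant_exactly_30pct_retained(self):
        succ = {f"p{i}": [True] * 10 for i in range(9)}
        succ["edge"] = [False] * 3 + [True] * 7  # exactly 30%: strict > rule keeps
        _, s2, log = apply_exclusions(_pointing_table(list(succ)), _shortcut_table(succ))
        assert "edge" in set(s2["participant_id"])
        assert not log.participants
        # but the 3 failures all sit on distinct trials failed by 1/10 < 30%
        assert not log.trials

    def test_trial_at_exactly_30pct_removed(self):
        """A trial failed by exactly 30% of participants is excluded
        (inclusive threshold), mirroring the one dropped study trial."""
        succ = {f"p{i}": [i >= 3] + [True] * 9 for i in range(10)}  # trial S-0: 3/10 fail
        _, s2, log = apply_exclusions(_pointing_table(list(succ)), _shortcut_table(succ))
        assert "S-0" not in set(s2["trial_id"])
        assert log.trials == [("S-0", pytest.approx(0.3))]

    def test_no_failures_is_identity(self):
        succ = {f"p{i}": [True] * 6 for i in range(5)}
        pt = _pointing_table(list(succ))
        sc = _shortcut_table(succ)
        p2, s2, log = apply_exclusions(pt, sc)
        pd.testing.assert_frame_equal(p2, pt)
        pd.testing.assert_frame_equal(s2, sc)
        assert not log.participants and not log.trials


class TestImputeFailed:
    def test_success_ratio_and_failure_constant(self):
        sc = _shortcut_table({"p1": [True, False]})
        out = impute_failed(sc, learned_route_eff=2.54)
        assert out["efficiency"].tolist() == pytest.approx([2.0, 2.54])

    def test_all_success_equals_plain_ratio(self):
        sc = _shortcut_table({"p1": [True] * 5})
        out = impute_failed(sc, learned_route_eff=2.54)
        expected = (sc["traveled_length_m"] / sc["shortest_length_m"]).tolist()
        assert out["efficiency"].tolist() == pytest.approx(expected)

    def test_learned_route_eff_must_exceed_one(self):
        with pytest.raises(ValueError, match="exceed 1"):
            impute_failed(_shortcut_table({"p1": [True]}), learned_route_eff=1.0)

    def test_imputation_never_lowers_mean_when_ceiling_dominates(self, rng):
        """When the imputation constant exceeds every successful ratio,
        imputing failures cannot decrease a participant's mean."""
        sc = _shortcut_table({"p1": [True, True, False, True, False]})
        sc.loc[sc["success"], "traveled_length_m"] = 5.0 * rng.uniform(1.0, 2.0, 3)
        out = impute_failed(sc, learned_route_eff=2.54)
        succ_only = out.loc[out["success"], "efficiency"].mean()
        assert out["efficiency"].mean() >= succ_only


class TestScoreParticipants:
    def test_simple_means(self):
        pt = pd.DataFrame(
            {
                "participant_id": ["p1"] * 3,
                "phase": ["I"] * 3,
                "trial_id": ["I-1", "I-2", "I-3"],
                "start_landmark": "a",
                "target_landmark": "b",
                "response_bearing_deg": [10.0, 20.0, 30.0],
                "true_bearing_deg": [0.0, 0.0, 0.0],
            }
        )
        eff = impute_failed(_shortcut_table({"p1": [True] * 2}), 2.54)
        eff["traveled_length_m"] = eff["shortest_length_m"]  # not used post-imputation
        scores = score_participants(pt, eff)
        assert scores.loc["p1", "pointing_error_I"] == pytest.approx(20.0)
        assert scores.loc["p1", "n_pointing_I"] == 3
        assert scores.loc["p1", "efficiency"] == pytest.approx(2.0)

    def test_row_order_invariance(self, rng):
        pt = _pointing_table(["p1", "p2", "p3"], n_trials=6)
        pt["response_bearing_deg"] = rng.uniform(0, 360, len(pt))
        eff = impute_failed(_shortcut_table({p: [True] * 4 for p in ("p1", "p2", "p3")}), 2.0)
        base = score_participants(pt, eff)
        shuffled = score_participants(
            pt.sample(frac=1, random_state=1), eff.sample(frac=1, random_state=2)
        )
        pd.testing.assert_frame_equal(base.sort_index(), shuffled.sort_index())

    def test_participant_in_one_table_warns(self):
        pt = _pointing_table(["p1", "p2"])
        eff = impute_failed(_shortcut_table({"p1": [True]}), 2.0)
        with pytest.warns(UserWarning, match="missing at least one measure"):
            scores = score_participants(pt, eff)
        assert np.isnan(scores.loc["p2", "efficiency"])
        assert scores.loc["p2", "pointing_error_I"] == pytest.approx(10.0)

    def test_uniform_guessing_mean_near_90(self, rng):
        n_p, n_t = 40, 250
        rows = {
            "participant_id": np.repeat([f"p{i}" for i in range(n_p)], n_t),
            "phase": "I",
            "trial_id": np.tile([f"I-{j}" for j in range(n_t)], n_p),
            "start_landmark": "a",
            "target_landmark": "b",
            "response_bearing_deg": rng.uniform(0, 360, n_p * n_t),
            "true_bearing_deg": rng.uniform(0, 360, n_p * n_t),
        }
        scores = score_participants(pd.DataFrame(rows), None)
        assert scores["pointing_error_I"].mean() == pytest.approx(90.0, abs=1.0)

    def test_matching_pairs_restriction(self):
        pt = _pointing_table(["p1"], n_trials=2)
        pt.loc[1, ["start_landmark", "target_landmark"]] = ["x", "y"]
        eff = impute_failed(_shortcut_table({"p1": [True]}), 2.0)
        full = score_participants(pt, eff)
        restricted = score_participants(pt, eff, matching_pairs_only=True)
        assert full.loc["p1", "n_pointing_I"] == 2
        assert restricted.loc["p1", "n_pointing_I"] == 1  # only the (a, b) trial

    def test_trial_matrix_shape(self, rng):
        pt = _pointing_table(["p1", "p2"], n_trials=5)
        mat = pointing_trial_matrix(pt, "I")
        assert mat.shape == (2, 5)
        assert (mat.to_numpy() == pytest.approx(10.0))
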