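"""Tests of the five-criterion chain scoring, including boundary locations
and the brute-force overtaking oracle."""

import numpy as np
import pytest

from crestchain.errors import InapplicableCriterionError
from crestchain.model import Arena
from crestchain.scoring import (
    ScoreConfig,
    detect_overtakings,
    score_all,
    score_cohesion,
    score_leader_front,
    score_path_completion,
    score_single_file,
)

from conftest import make_trajectory


def two_cell_static(separation, n_frames=5):
    y = np.zeros((n_frames, 2))
    y[:, 0] = separation
    return make_trajectory(y, "LF")


class TestCohesion:
    def test_pass_below_threshold(self):
        res = score_cohesion(two_cell_static(50.0))
        assert res["pass"] and res["max_adjacent_gap"] == pytest.approx(50.0)

    def test_fail_above_threshold(self):
        assert not score_cohesion(two_cell_static(60.0))["pass"]

    def test_boundary_is_at_57um(self):
        lo, hi = 1.0, 200.0
        while hi - lo > 0.01:
            mid = (lo + hi) / 2
            if score_cohesion(two_cell_static(mid))["pass"]:
                lo = mid
            else:
                hi = mid
        assert (lo + hi) / 2 == pytest.approx(57.0, abs=0.05)

    def test_single_cell_is_inapplicable(self):
        traj = make_trajectory(np.zeros((5, 1)), "L")
        with pytest.raises(InapplicableCriterionError):
            score_cohesion(traj)

    def test_gap_uses_chain_order_not_cell_order(self):
        # cells given out of ventral order: adjacent gaps follow y-ranking
        y = np.tile([0.0, 80.0, 40.0], (4, 1))
        res = score_cohesion(make_trajectory(y, "FLF"))
        assert res["max_adjacent_gap"] == pytest.approx(40.0)
        assert res["pass"]

    def test_monotone_in_threshold(self):
        traj = two_cell_static(57.5)
        assert not score_cohesion(traj, ScoreConfig())["pass"]
        assert score_cohesion(traj, ScoreConfig(cohesion_max=58.0))["pass"]


class TestSingleFile:
    def _fraction_fixture(self, k, n=100):
        """Exactly k of n frames are single file."""
        y = np.zeros((n, 2))
        x = np.zeros((n, 2))
        in_line = np.arange(n) < k
        y[in_line, 0] = 20.0
        x[~in_line, 0] = 10.0  # abreast: level, in contact
        return make_trajectory(y, "LF", x=x)

    def test_collinear_chain_scores_one(self):
        y = np.tile([30.0, 15.0, 0.0], (10, 1))
        res = score_single_file(make_trajectory(y, "LFF"))
        assert res["pass"] and res["fraction"] == 1.0

    def test_79_of_100_frames_fails(self):
        res = score_single_file(self._fraction_fixture(79))
        assert res["fraction"] == pytest.approx(0.79)
        assert not res["pass"]

    def test_threshold_flips_at_80_percent(self):
        passing = [
            k for k in range(70, 91)
            if score_single_file(self._fraction_fixture(k))["pass"]
        ]
        assert min(passing) == 80


def brute_force_overtakers(traj, cfg):
    """Frame-by-frame rank oracle for sustained overtaking events."""
    y = traj.positions[:, :, 1]
    front = int(np.argmax(y[0]))
    followers = [k for k, i in enumerate(traj.identities) if i.value == "follower"]
    out = set()
    for j in followers:
        if j == front:
            continue
        run = 0
        for t in range(y.shape[0]):
            run = run + 1 if y[t, j] > y[t, front] + cfg.overtake_delta else 0
            if run >= cfg.overtake_min_frames:
                out.add(j)
                break
    return out


class TestOvertaking:
    def test_leader_always_front_is_category_zero(self):
        y = np.linspace(0, 50, 20)[:, None] + np.array([30.0, 15.0, 0.0])
        ev = detect_overtakings(make_trajectory(y, "LFF"))
        assert ev["overtaken_category"] == "0"

    def test_single_sustained_crossing_is_category_one(self):
        y = np.zeros((20, 2))
        y[:, 0] = 10.0
        y[10:, 1] = 20.0  # follower jumps ahead and stays 10 frames
        ev = detect_overtakings(make_trajectory(y, "LF"))
        assert ev["overtaken_category"] == "1"
        assert ev["overtakers"] == [1]

    def test_two_distinct_overtakers_is_category_many(self):
        y = np.zeros((30, 3))
        y[:, 0] = 10.0
        y[10:, 1] = 20.0
        y[20:, 2] = 25.0
        ev = detect_overtakings(make_trajectory(y, "LFF"))
        assert ev["overtaken_category"] == ">1"

    def test_brief_crossing_below_min_frames_ignored(self):
        y = np.zeros((20, 2))
        y[:, 0] = 10.0
        y[5:7, 1] = 20.0  # 2 frames < overtake_min_frames
        ev = detect_overtakings(make_trajectory(y, "LF"))
        assert ev["overtaken_category"] == "0"

    @pytest.mark.parametrize("n_cells", [2, 3, 5])
    def test_agrees_with_brute_force_oracle(self, n_cells):
        cfg = ScoreConfig()
        rng = np.random.default_rng(123)
        for _ in range(40):
            y = np.cumsum(rng.normal(0.3, 3.0, size=(50, n_cells)), axis=0)
            y[0] = np.arange(n_cells)[::-1] * 12.0
            ident = "L" + "F" * (n_cells - 1)
            traj = make_trajectory(y, ident)
            ev = detect_overtakings(traj, cfg)
            assert set(ev["overtakers"]) == brute_force_overtakers(traj, cfg)


class TestLeaderFrontAndCompletion:
    def test_ballistic_leader_retains_front(self):
        y = np.linspace(0, 100, 30)[:, None] + np.array([20.0, 10.0, 0.0])
        res = score_leader_front(make_trajectory(y, "LFF"))
        assert res["pass"] and res["retention_fraction"] == 1.0

    def test_no_leader_cannot_pass(self):
        y = np.tile([20.0, 0.0], (10, 1))
        res = score_leader_front(make_trajectory(y, "FF"))
        assert not res["pass"] and res["retention_fraction"] == 0.0

    def test_over_migration_flag(self):
        arena = Arena()
        cfg = ScoreConfig()
        y = np.tile([0.0, -15.0], (5, 1))
        y[-1, 0] = arena.y_end + 2 * cfg.overmigration_margin
        y[:, 0] = np.linspace(0, arena.y_end + 2 * cfg.overmigration_margin, 5)
        res = score_path_completion(make_trajectory(y, "LF"), arena, cfg)
        assert res["pass"] and res["over_migrated"]

    def test_chain_stalling_at_ntnot_fails_completion(self):
        arena = Arena()
        y = np.tile([arena.y_ntnot, arena.y_ntnot - 15.0], (10, 1))
        res = score_path_completion(make_trajectory(y, "LF"), arena)
        assert not res["pass"] and not res["over_migrated"]


class TestScoreAll:
    def _good_fixture(self):
        # leader advances to the end, one sustained follower swap, tight chain
        n = 60
        lead = np.linspace(20, 155, n)
        f1 = lead - 12.0
        f2 = lead - 24.0
        f1_, f2_ = f1.copy(), f2.copy()
        f1_[30:], f2_[30:] = f2[30:], f1[30:]  # sustained follower swap
        y = np.stack([lead, f1_, f2_], axis=1)
        return make_trajectory(y, "LFF")

    def test_fixture_passing_all_five(self):
        report = score_all(self._good_fixture(), Arena())
        assert report.all_pass, report.passes()

    def test_single_wide_gap_fails_via_cohesion(self):
        traj = self._good_fixture()
        traj.positions[10, 2, 1] -= 50.0  # widen one adjacent gap past 57
        report = score_all(traj, Arena())
        assert not report.cohesion["pass"]
        assert not report.all_pass

    def test_scoring_invariant_to_x_translation(self):
        traj = self._good_fixture()
        report1 = score_all(traj, Arena())
        traj.positions[:, :, 0] += 3.0
        report2 = score_all(traj, Arena())
        assert report1.passes() == report2.passes()
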