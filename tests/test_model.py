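"""Unit and property tests of the discrete-element chain simulator."""

import itertools

import numpy as np
import pytest

import crestchain as cx
from crestchain.errors import ConfigurationError
from crestchain.model import (
    Arena,
    Composition,
    Identity,
    ModelParams,
    coattraction_displacement,
    init_chain,
    resolve_cil,
    simulate,
    step,
)

FREE = dict(cil_mode="off", coattraction_strength="off", zeta=0.0)


class TestInitChain:
    def test_places_pattern_order_without_overlap(self, default_arena):
        params = ModelParams()
        agents = init_chain(
            Composition.from_string("LFFF"), default_arena, params, seed=0
        )
        assert len(agents) == 4
        assert agents[0].identity is Identity.LEADER
        assert all(a.identity is Identity.FOLLOWER for a in agents[1:])
        # front cell is most ventral, inside the premigratory band
        ys = [a.position[1] for a in agents]
        assert ys[0] == max(ys)
        assert 0 <= ys[0] <= default_arena.y_premigratory
        for a, b in itertools.combinations(agents, 2):
            assert np.linalg.norm(a.position - b.position) >= a.radius + b.radius

    def test_same_seed_reproduces_agents(self, default_arena):
        params = ModelParams()
        a1 = init_chain(Composition.preset("1:3"), default_arena, params, seed=42)
        a2 = init_chain(Composition.preset("1:3"), default_arena, params, seed=42)
        for x, y in zip(a1, a2):
            assert np.array_equal(x.position, y.position)
            assert np.array_equal(x.heading, y.heading)

    def test_chain_exceeding_band_capacity_is_config_error(self, default_arena):
        params = ModelParams(
            cell_radius={Identity.LEADER: 5.7, Identity.FOLLOWER: 5.7}
        )
        # stacked length 20 cells x 11.4 um (+ packing gaps) exceeds capacity
        with pytest.raises(ConfigurationError, match=r"needs 2\d\d(\.\d)? um"):
            init_chain(
                Composition.from_string("L" * 20), default_arena, params, seed=0
            )

    def test_headings_are_unit_and_ventral(self, default_arena):
        agents = init_chain(
            Composition.preset("1:3"), default_arena, ModelParams(), seed=3
        )
        for a in agents:
            assert abs(np.linalg.norm(a.heading) - 1) < 1e-9
            assert a.heading[1] > 0.9


class TestStep:
    def test_free_motion_is_speed_times_dt(self, default_arena):
        params = ModelParams(**FREE)
        agent = cx.AgentState(
            agent_id=0,
            identity=Identity.LEADER,
            position=np.array([9.0, 50.0]),
            heading=np.array([0.0, 1.0]),
            radius=5.7,
            speed=0.7,
        )
        out = step([agent], params, default_arena, np.random.default_rng(0))
        np.testing.assert_allclose(
            out[0].position, [9.0, 50.0 + 0.7 * params.dt], atol=1e-12
        )

    def test_volume_exclusion_separates_overlapping_pair(self, default_arena):
        params = ModelParams(
            **FREE, base_speed={Identity.LEADER: 0.0, Identity.FOLLOWER: 0.0}
        )
        mk = lambda i, y: cx.AgentState(
            agent_id=i,
            identity=Identity.FOLLOWER,
            position=np.array([9.0, y]),
            heading=np.array([0.0, 1.0]),
            radius=4.79,
            speed=0.0,
        )
        out = step([mk(0, 50.0), mk(1, 53.0)], params, default_arena,
                   np.random.default_rng(0))
        dist = np.linalg.norm(out[0].position - out[1].position)
        assert dist >= 2 * 4.79 - params.exclusion_tolerance

    def test_wall_reflection_turns_heading_inward(self, default_arena):
        params = ModelParams(**FREE)
        agent = cx.AgentState(
            agent_id=0,
            identity=Identity.LEADER,
            position=np.array([default_arena.width - 5.71, 50.0]),
            heading=np.array([1.0, 0.0]),
            radius=5.7,
            speed=0.7,
        )
        out = step([agent], params, default_arena, np.random.default_rng(0))
        assert out[0].position[0] <= default_arena.width - out[0].radius
        assert out[0].heading[0] <= 0


class TestResolveCil:
    def _pair(self, ids, headings, offset=10.0):
        a = cx.AgentState(0, ids[0], np.array([0.0, 0.0]),
                          np.asarray(headings[0], float), 5.0, 0.5)
        b = cx.AgentState(1, ids[1], np.array([0.0, offset]),
                          np.asarray(headings[1], float), 5.0, 0.5)
        return a, b

    def test_differential_mode_ignores_same_identity(self):
        params = ModelParams(cil_mode="differential")
        a, b = self._pair((Identity.FOLLOWER, Identity.FOLLOWER),
                          ([0, 1], [0, -1]))
        ha, hb = resolve_cil(a, b, params)
        np.testing.assert_array_equal(ha, a.heading)
        np.testing.assert_array_equal(hb, b.heading)

    def test_head_on_collision_leader_turns_more(self):
        params = ModelParams(
            cil_mode="all_pairs",
            cil_intensity={Identity.LEADER: "high", Identity.FOLLOWER: "low"},
        )
        leader, follower = self._pair(
            (Identity.LEADER, Identity.FOLLOWER), ([0, 1], [0, -1])
        )
        hl, hf = resolve_cil(leader, follower, params)
        turn = lambda old, new: abs(
            np.arctan2(old[0] * new[1] - old[1] * new[0], np.dot(old, new))
        )
        assert turn(leader.heading, hl) > turn(follower.heading, hf)
        assert abs(np.linalg.norm(hl) - 1) < 1e-9
        assert abs(np.linalg.norm(hf) - 1) < 1e-9

    def test_zero_intensity_leaves_headings_unchanged(self):
        params = ModelParams(
            cil_mode="all_pairs",
            cil_intensity={Identity.LEADER: "off", Identity.FOLLOWER: "off"},
        )
        a, b = self._pair((Identity.LEADER, Identity.FOLLOWER), ([0, 1], [0, -1]))
        ha, hb = resolve_cil(a, b, params)
        np.testing.assert_array_equal(ha, a.heading)
        np.testing.assert_array_equal(hb, b.heading)

    def test_turns_point_away_from_partner(self):
        params = ModelParams(cil_mode="all_pairs")
        a, b = self._pair((Identity.LEADER, Identity.FOLLOWER), ([0, 1], [0, -1]))
        ha, hb = resolve_cil(a, b, params)
        # partner b sits ventral of a: a must turn dorsal-ward, b ventral-ward
        assert ha[1] < a.heading[1]
        assert hb[1] > b.heading[1]


class TestCoattraction:
    def test_isolated_cell_gets_zero(self):
        params = ModelParams()
        focal = cx.AgentState(0, Identity.FOLLOWER, np.zeros(2),
                              np.array([0.0, 1.0]), 4.79, 0.5)
        np.testing.assert_array_equal(
            coattraction_displacement(focal, [], params), np.zeros(2)
        )

    def test_pair_within_range_is_antisymmetric(self):
        params = ModelParams()
        a = cx.AgentState(0, Identity.FOLLOWER, np.array([0.0, 0.0]),
                          np.array([0.0, 1.0]), 4.79, 0.5)
        b = cx.AgentState(1, Identity.FOLLOWER, np.array([0.0, 30.0]),
                          np.array([0.0, 1.0]), 4.79, 0.5)
        da = coattraction_displacement(a, [b], params)
        db = coattraction_displacement(b, [a], params)
        np.testing.assert_allclose(da, -db, atol=1e-12)
        assert np.linalg.norm(da) > 0

    def test_beyond_range_gives_zero(self):
        params = ModelParams()
        gap = params.coattraction_range + 1.0
        a = cx.AgentState(0, Identity.FOLLOWER, np.array([0.0, 0.0]),
                          np.array([0.0, 1.0]), 4.79, 0.5)
        b = cx.AgentState(1, Identity.FOLLOWER, np.array([0.0, gap]),
                          np.array([0.0, 1.0]), 4.79, 0.5)
        np.testing.assert_array_equal(
            coattraction_displacement(a, [b], params), np.zeros(2)
        )
        np.testing.assert_array_equal(
            coattraction_displacement(b, [a], params), np.zeros(2)
        )

    def test_magnitude_monotone_in_strength(self):
        a = cx.AgentState(0, Identity.FOLLOWER, np.array([0.0, 0.0]),
                          np.array([0.0, 1.0]), 4.79, 0.5)
        b = cx.AgentState(1, Identity.FOLLOWER, np.array([0.0, 30.0]),
                          np.array([0.0, 1.0]), 4.79, 0.5)
        mags = [
            np.linalg.norm(
                coattraction_displacement(
                    a, [b], ModelParams(coattraction_strength=level)
                )
            )
            for level in ("off", "low", "medium", "high")
        ]
        assert mags == sorted(mags)


class TestSimulate:
    def test_static_limit_keeps_all_frames_identical(self, default_arena):
        params = ModelParams(
            **FREE,
            base_speed={Identity.LEADER: 0.0, Identity.FOLLOWER: 0.0},
            n_steps=50,
        )
        traj = simulate(Composition.preset("1:3"), default_arena, params, seed=1)
        for frame in traj.positions[1:]:
            np.testing.assert_array_equal(frame, traj.positions[0])

    def test_same_seed_bitwise_identical(self, default_arena, quick_params):
        t1 = simulate(Composition.preset("1:3"), default_arena, quick_params, seed=9)
        t2 = simulate(Composition.preset("1:3"), default_arena, quick_params, seed=9)
        assert np.array_equal(t1.positions, t2.positions)

    def test_free_single_leader_matches_ballistic_closed_form(self, default_arena):
        params = ModelParams(**FREE, n_steps=100)
        traj = simulate(Composition.from_string("L"), default_arena, params, seed=3)
        y0 = traj.positions[0, 0, 1]
        expected = y0 + params.base_speed[Identity.LEADER] * 100 * params.dt
        assert abs(traj.positions[-1, 0, 1] - expected) < 1e-9

    def test_frame_count_and_times(self, default_arena, quick_params):
        traj = simulate(Composition.preset("1:3"), default_arena, quick_params, seed=0)
        assert traj.n_frames == quick_params.n_steps // quick_params.sample_every + 1
        dt = np.diff(traj.times)
        assert np.allclose(dt, quick_params.dt * quick_params.sample_every)

    def test_exchangeability_of_identical_followers(self, default_arena, quick_params):
        # swapping two follower entries in the pattern is a no-op
        t1 = simulate(Composition.from_string("LFFF"), default_arena, quick_params, seed=4)
        t2 = simulate(Composition.from_string("LFFF"), default_arena, quick_params, seed=4)
        assert np.array_equal(t1.positions, t2.positions)

    @pytest.mark.parametrize("comp", ["LFFFLFFF", "FFFFFFFF", "LLLLLLLL"])
    def test_containment_and_overlap_invariants(self, default_arena, comp):
        params = ModelParams(n_steps=300)
        traj = simulate(Composition.from_string(comp), default_arena, params, seed=11)
        x = traj.positions[:, :, 0]
        y = traj.positions[:, :, 1]
        assert np.all(x >= -1e-9) and np.all(x <= default_arena.width + 1e-9)
        assert np.all(y >= default_arena.y_dorsal - 1e-9)
        # deformable-cell overlap bound (see methods note)
        r = traj.radii
        for i, j in itertools.combinations(range(traj.n_cells), 2):
            d = np.linalg.norm(traj.positions[:, i] - traj.positions[:, j], axis=1)
            assert d.min() >= r[i] + r[j] - 6.0
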