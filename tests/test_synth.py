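"""Tests of the synthetic-data generators: parameter fidelity, determinism
and round trips through the consuming analyses."""

import numpy as np
import pytest
from scipy import stats

from crestchain.cellcycle import durations_from_states, onset_phase
from crestchain.errors import ConfigurationError
from crestchain.io import read_track_table, write_track_table
from crestchain.lda import fit_lda, rank_features
from crestchain.metrics import summarize
from crestchain.synth import (
    GeneratorConfig,
    MixtureSpec,
    PhaseSpec,
    TrackSpec,
    gen_cellcycle,
    gen_division_areas,
    gen_phase_sequences,
    gen_tracks,
    notch_inhibited_config,
)


class TestGenCellcycle:
    def test_leader_s_phase_mean_within_two_sem(self):
        x = gen_cellcycle("leader", "S", 10_000, seed=0)
        sem = 1.3 / np.sqrt(10_000)
        assert abs(x.mean() - 8.7) < 2 * sem

    def test_degenerate_sd_collapses_to_mean(self):
        cfg = GeneratorConfig(
            cellcycle={"leader": {"G1": PhaseSpec(3.2, 1e-6)}}
        )
        x = gen_cellcycle("leader", "G1", 100, cfg, seed=1)
        np.testing.assert_allclose(x, 3.2, atol=1e-4)

    def test_follower_g1_mixture_mass_below_midpoint(self):
        # analytic mixture CDF at the 5 h cut
        spec = GeneratorConfig().cellcycle["follower"]["G1"]
        expected = spec.minor_weight * stats.norm.cdf(
            5.0, spec.minor_mean, spec.minor_sd
        ) + (1 - spec.minor_weight) * stats.norm.cdf(
            5.0, spec.major_mean, spec.major_sd
        )
        x = gen_cellcycle("follower", "G1", 10_000, seed=2)
        assert np.mean(x < 5.0) == pytest.approx(expected, abs=0.02)

    def test_follower_g1_mixture_reproduces_printed_mean_and_sd(self):
        x = gen_cellcycle("follower", "G1", 50_000, seed=3)
        assert x.mean() == pytest.approx(7.4, abs=0.05)
        assert x.std() == pytest.approx(2.7, abs=0.05)

    def test_all_draws_positive(self):
        for ident in ("leader", "follower"):
            for phase in ("G1", "S", "G2", "M"):
                assert (gen_cellcycle(ident, phase, 2000, seed=4) > 0).all()

    def test_deterministic_per_seed(self):
        a = gen_cellcycle("leader", "G1", 50, seed=9)
        b = gen_cellcycle("leader", "G1", 50, seed=9)
        np.testing.assert_array_equal(a, b)

    def test_notch_inhibited_config_collapses_dispersion(self):
        cfg = notch_inhibited_config()
        x = gen_cellcycle("follower", "G1", 20_000, cfg, seed=5)
        assert x.std() == pytest.approx(1.42, abs=0.05)
        assert x.mean() == pytest.approx(7.4, abs=0.05)


class TestGenPhaseSequences:
    def test_three_hour_g1_gives_36_frames(self):
        cfg = GeneratorConfig(
            cellcycle={
                "leader": {
                    "G1": PhaseSpec(3.0, 1e-9),
                    "S": PhaseSpec(2.0, 1e-9),
                    "G2": PhaseSpec(1.0, 1e-9),
                    "M": PhaseSpec(0.5, 1e-9),
                }
            }
        )
        s = gen_phase_sequences("leader", 1, cfg, seed=0)[0]
        assert s.labels.count("G1") == 36 + 1  # trailing G1 frame closes the M run

    def test_round_trip_recovers_durations_within_one_frame(self):
        sequences = gen_phase_sequences("leader", 30, seed=1)
        cfg = GeneratorConfig().cellcycle["leader"]
        for s in sequences:
            d = durations_from_states(s)
            for phase in ("G1", "S", "G2", "M"):
                assert phase in d.durations
                assert d.durations[phase] > 0
            # quantisation error at most half a frame per boundary
            total_from_phases = sum(d.durations.values())
            assert d.total == pytest.approx(total_from_phases, abs=4 * 5 / 60)

    def test_exact_durations_quantise_to_nearest_frame(self):
        cfg = GeneratorConfig(
            cellcycle={
                "leader": {
                    "G1": PhaseSpec(3.2, 1e-9),
                    "S": PhaseSpec(8.7, 1e-9),
                    "G2": PhaseSpec(1.6, 1e-9),
                    "M": PhaseSpec(0.6, 1e-9),
                }
            }
        )
        s = gen_phase_sequences("leader", 1, cfg, seed=2)[0]
        d = durations_from_states(s)
        for phase, expected in (("G1", 3.2), ("S", 8.7), ("G2", 1.6), ("M", 0.6)):
            assert d.durations[phase] == pytest.approx(expected, abs=5 / 60)

    def test_onset_in_s_fraction_matches_configured_probability(self):
        n = 4000
        sequences = gen_phase_sequences("leader", n, seed=3, with_onset=True)
        classes = [onset_phase(s) for s in sequences]
        frac = np.mean([c == "S_or_G2" for c in classes])
        sem = np.sqrt(0.79 * 0.21 / n)
        assert abs(frac - 0.79) < 3 * sem

    def test_left_censoring_keeps_sequences_valid(self):
        sequences = gen_phase_sequences(
            "follower", 20, seed=4, left_censor=True, with_onset=True
        )
        for s in sequences:
            if s.onset_frame is not None:
                assert 0 <= s.onset_frame < len(s.labels)


class TestGenTracks:
    def test_pure_ventral_bias_gives_unit_directionality(self):
        cfg = GeneratorConfig(
            tracks={
                "leader": TrackSpec(25.0, 0.0, 1.0, 0.0),
                "follower": TrackSpec(15.0, 0.0, 1.0, 0.0),
            }
        )
        table = gen_tracks(2, 2, cfg, n_frames=30, seed=0)
        per_cell, _ = summarize(table)
        np.testing.assert_allclose(per_cell["directionality"], 1.0, atol=1e-12)

    def test_default_contrasts_put_ventral_distance_first_in_lda(self):
        table = gen_tracks(20, 60, n_frames=96, seed=1)
        per_cell, _ = summarize(table)
        lead = per_cell[per_cell.identity == "leader"]
        foll = per_cell[per_cell.identity == "follower"]
        assert lead["ventral_distance"].mean() > foll["ventral_distance"].mean()
        features = per_cell[
            ["ventral_distance", "mean_speed", "directionality", "identity"]
        ].dropna()
        assert rank_features(fit_lda(features))[0] == "ventral_distance"

    def test_zero_speed_keeps_cells_in_place(self):
        cfg = GeneratorConfig(
            tracks={
                "leader": TrackSpec(0.0, 0.0, 1.0, 0.0),
                "follower": TrackSpec(0.0, 0.0, 1.0, 0.0),
            }
        )
        table = gen_tracks(1, 1, cfg, n_frames=10, seed=2)
        per_cell, _ = summarize(table)
        assert (per_cell["mean_speed"] == 0).all()
        assert (per_cell["ventral_distance"] == 0).all()

    def test_output_passes_track_table_validation(self, tmp_path):
        table = gen_tracks(3, 9, n_frames=20, seed=3)
        path = tmp_path / "tracks.csv"
        write_track_table(table, path)
        loaded = read_track_table(path)
        assert len(loaded) == 12 * 20

    def test_deterministic_per_seed(self):
        t1 = gen_tracks(2, 2, n_frames=10, seed=7)
        t2 = gen_tracks(2, 2, n_frames=10, seed=7)
        assert t1.equals(t2)


class TestGenDivisionAreas:
    def test_asymmetric_means_within_two_sem(self):
        pairs = gen_division_areas("asym", 10_000, seed=0)
        assert abs(pairs["daughter_a_um2"].mean() - 102) < 2 * 20 / 100
        assert abs(pairs["daughter_b_um2"].mean() - 72) < 2 * 9 / 100

    def test_symmetric_pairs_have_zero_mean_difference(self):
        pairs = gen_division_areas("sym", 10_000, seed=1)
        diff = pairs["daughter_a_um2"] - pairs["daughter_b_um2"]
        sem = diff.std() / np.sqrt(len(diff))
        assert abs(diff.mean()) < 3 * sem

    def test_unknown_kind_rejected(self):
        with pytest.raises(ConfigurationError):
            gen_division_areas("weird", 5, seed=0)

    def test_small_asymmetric_samples_usually_significant(self):
        # power check mirroring a 9-pair comparison
        from crestchain.cellcycle import auto_compare

        hits = 0
        for seed in range(100):
            pairs = gen_division_areas("asym", 9, seed=seed)
            res = auto_compare(
                pairs["daughter_a_um2"].to_numpy(),
                pairs["daughter_b_um2"].to_numpy(),
            )
            hits += res["p"] < 0.05
        assert hits > 80


class TestConfigValidation:
    def test_mixture_weight_bounds(self):
        with pytest.raises(ConfigurationError):
            MixtureSpec(0.6, 3.2, 0.6, 8.9, 1.1)

    def test_track_bias_bounds(self):
        with pytest.raises(ConfigurationError):
            TrackSpec(10.0, 1.0, 1.5, 0.2)

    def test_positive_sd_required(self):
        with pytest.raises(ConfigurationError):
            PhaseSpec(3.0, 0.0)
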