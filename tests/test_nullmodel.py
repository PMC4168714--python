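"""Null-model calibration: decoys, folding, simulated reactivities,
distribution fitting and p-values."""

import numpy as np
import pytest
from scipy import stats

from oracle import brute_force_nussinov
from probealign import (
    AlignParams,
    DecoySpec,
    GammaNull,
    ReactivityTrack,
    align,
    assign_structure,
    calibrate,
    fit_null,
    generate_decoy,
    p_value,
    sample_null_scores,
    simulate_reactivities,
)
from probealign.io import read_null_json, write_null_json
from probealign.reactivity import default_shape_model


class TestDecoys:
    def test_seed_determinism(self):
        spec = DecoySpec(1, 100, 0.5, seed=7)
        assert generate_decoy(spec) == generate_decoy(spec)

    def test_alphabet(self):
        seq = generate_decoy(DecoySpec(3, 80, 0.6, seed=2))
        assert set(seq) <= set("ACGU")
        assert len(seq) == 240

    @pytest.mark.parametrize("gc", [0.3, 0.5, 0.7])
    def test_gc_content_hits_target(self, gc):
        seq = generate_decoy(DecoySpec(50, 200, gc, seed=1))
        realized = (seq.count("G") + seq.count("C")) / len(seq)
        assert realized == pytest.approx(gc, abs=0.05)


class TestAssignStructure:
    def test_unpairable_sequence(self):
        pairedness, table = assign_structure("AAAA")
        assert table == {}
        assert pairedness.tolist() == [1, 1, 1, 1]

    def test_gc_stem(self):
        pairedness, table = assign_structure("GGGAAACCC")
        assert len(table) // 2 == 3
        assert pairedness.tolist() == [0, 0, 0, 1, 1, 1, 0, 0, 0]

    def test_matches_exhaustive_recursion_on_random_sequences(self):
        rng = np.random.default_rng(6)
        for _ in range(30):
            m = int(rng.integers(5, 16))
            seq = "".join("ACGU"[i] for i in rng.integers(0, 4, m))
            _, table = assign_structure(seq)
            assert len(table) // 2 == brute_force_nussinov(seq)

    def test_involution_and_min_loop(self):
        seq = generate_decoy(DecoySpec(1, 120, 0.5, seed=9))
        _, table = assign_structure(seq)
        for i, j in table.items():
            assert table[j] == i
            assert abs(i - j) >= 4


class TestSimulatedReactivities:
    def test_seed_determinism(self):
        pairedness = np.array([0, 1, 0, 1, 1], dtype=np.int8)
        t1 = simulate_reactivities(pairedness, seed=3)
        t2 = simulate_reactivities(pairedness, seed=3)
        np.testing.assert_array_equal(t1.values, t2.values)
        assert t1.defined_mask.all()

    def test_sample_means_match_densities(self):
        model = default_shape_model()
        all_paired = np.zeros(10000, dtype=np.int8)
        track = simulate_reactivities(all_paired, model, seed=4)
        # paired density is Exponential(mean 0.15): se = mean/sqrt(n)
        se = 0.15 / np.sqrt(10000)
        assert abs(track.values.mean() - 0.15) < 3 * se

    def test_unpaired_positions_more_reactive(self):
        pairedness = np.tile([0, 1], 5000).astype(np.int8)
        track = simulate_reactivities(pairedness, seed=5)
        paired_mean = track.values[::2].mean()
        unpaired_mean = track.values[1::2].mean()
        assert unpaired_mean > paired_mean


class TestNullScores:
    def test_reproducible_and_right_length(self, hairpin_profile):
        spec = DecoySpec(seed=8, segment_length=80)
        params = AlignParams()
        s1 = sample_null_scores(hairpin_profile, spec, params, n_samples=120)
        s2 = sample_null_scores(hairpin_profile, spec, params, n_samples=120)
        np.testing.assert_array_equal(s1, s2)
        assert len(s1) == 120

    def test_true_signal_beats_decoys(self, hairpin_profile):
        spec = DecoySpec(seed=8, segment_length=80)
        params = AlignParams()
        null_scores = sample_null_scores(hairpin_profile, spec, params, n_samples=150)
        # profile vs its own consensus with concordant reactivities
        consensus = hairpin_profile.consensus()
        track = simulate_reactivities(hairpin_profile.pairedness, seed=1)
        true_score = align(hairpin_profile, consensus, track, params).combined_score
        assert true_score > null_scores.mean()

    def test_too_few_samples_rejected(self, hairpin_profile):
        with pytest.raises(ValueError):
            sample_null_scores(hairpin_profile, DecoySpec(seed=1), AlignParams(), 50)


class TestFitNull:
    def test_gamma_parameter_recovery(self):
        draws = np.random.default_rng(1).gamma(3.0, 2.0, 5000)
        null = fit_null(draws)
        assert 2.7 <= null.shape <= 3.3
        assert 1.8 <= null.scale <= 2.2

    def test_normal_data_prefers_normal_in_report(self):
        draws = np.random.default_rng(2).normal(0.0, 1.0, 5000)
        null = fit_null(draws)
        assert set(null.fit_report) == {"normal", "gumbel", "gev", "gamma"}
        assert null.fit_report["normal"] < null.fit_report["gamma"]

    def test_probability_integral_transform_uniform(self):
        draws = np.random.default_rng(3).gamma(4.0, 1.5, 5000) - 2.0
        null = fit_null(draws)
        pvals = [p_value(s, null) for s in draws]
        d = stats.kstest(pvals, "uniform").statistic
        assert d < 0.05

    def test_negative_scores_supported(self):
        draws = np.random.default_rng(4).gamma(2.0, 1.0, 1000) - 10.0
        null = fit_null(draws)
        assert null.loc < draws.min()
        assert 0.0 <= p_value(-5.0, null) <= 1.0

    def test_degenerate_scores_fatal(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_null(np.full(500, 3.0))

    def test_scale_equivariance(self):
        draws = np.random.default_rng(5).gamma(3.0, 2.0, 4000)
        n1 = fit_null(draws)
        n2 = fit_null(3.0 * draws)
        assert n2.scale / n1.scale == pytest.approx(3.0, rel=0.05)
        assert n2.shape == pytest.approx(n1.shape, rel=0.05)


@pytest.fixture()
def null():
    draws = np.random.default_rng(6).gamma(3.0, 2.0, 2000)
    return fit_null(draws)


class TestPValue:

    def test_location_gives_one(self, null):
        assert p_value(null.loc, null) == pytest.approx(1.0)

    def test_infinity_gives_zero(self, null):
        assert p_value(1e9, null) == pytest.approx(0.0, abs=1e-12)

    def test_monotone_decreasing(self, null):
        grid = np.linspace(null.loc, null.loc + 30, 200)
        pvals = [p_value(s, null) for s in grid]
        assert all(a >= b for a, b in zip(pvals, pvals[1:]))


class TestCalibratePipeline:
    def test_json_round_trip(self, hairpin_profile, tmp_path):
        null = calibrate(
            hairpin_profile, AlignParams(), DecoySpec(seed=2, segment_length=60),
            n_samples=150,
        )
        p = tmp_path / "null.json"
        write_null_json(null, p)
        back = read_null_json(p)
        assert back.shape == null.shape
        assert back.fit_report == pytest.approx(null.fit_report)
        assert isinstance(back, GammaNull)

    def test_reactivity_track_undefined_slots_hold_nan(self):
        track = ReactivityTrack(np.array([0.5, 7.0]), np.array([True, False]))
        assert np.isnan(track.values[1])
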