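"""The alignment engine: sigma, the DP against a brute-force oracle,
traceback, consistency bonus, and multi-hit scanning."""

import numpy as np
import pytest

from oracle import brute_force_semiglobal
from probealign import (
    AlignParams,
    Profile,
    ReactivityTrack,
    StructuralScoringConfig,
    align,
    default_subst_matrix,
    scan,
    sigma,
)
from probealign.align import match_matrix
from conftest import random_profile, random_target


def random_instance(rng, mode):
    n = int(rng.integers(1, 7))
    m = int(rng.integers(1, 9))
    prof = random_profile(rng, n)
    target = random_target(rng, m)
    vals = rng.uniform(0, 2, m)
    defined = rng.random(m) < 0.8
    track = ReactivityTrack(np.where(defined, vals, np.nan), defined)
    params = AlignParams(
        alpha=float(rng.uniform(0, 2)),
        beta=float(rng.uniform(0, 4)),
        gap_open=-float(rng.uniform(0, 6)),
        gap_extend=-float(rng.uniform(0, 2)),
        scoring=StructuralScoringConfig(mode=mode),
        use_consistency=False,
    )
    return prof, target, track, params


class TestSigma:
    def test_one_hot_column_returns_matrix_entry(self):
        subst = default_subst_matrix()
        col = np.array([1.0, 0, 0, 0, 0, 0])
        assert sigma(col, "A", subst) == subst[("A", "A")] == 2.0

    def test_two_term_mixture(self):
        subst = default_subst_matrix()
        col = np.array([0.5, 0, 0, 0, 0, 0.5])
        expected = 0.5 * subst[("A", "A")] + 0.5 * subst[("-", "A")]
        assert sigma(col, "A", subst) == pytest.approx(expected)  # 0.5*2 - 0.5

    def test_uniform_column_averages_the_matrix(self):
        subst = default_subst_matrix()
        col = np.array([0.25, 0.25, 0.25, 0.25, 0, 0])
        expected = np.mean([subst[(x, "G")] for x in "ACGU"])  # (2-1-1-1)/4
        assert sigma(col, "G", subst) == pytest.approx(expected) == -0.25


class TestDPOracle:
    @pytest.mark.parametrize("mode", ["simplified", "protocol_specific"])
    def test_dp_equals_brute_force_on_random_instances(self, mode):
        rng = np.random.default_rng(42 if mode == "simplified" else 43)
        for _ in range(120):
            prof, target, track, params = random_instance(rng, mode)
            hit = align(prof, target, track, params)
            mm = match_matrix(prof, target, track, params)
            expected = brute_force_semiglobal(mm, params.gap_open, params.gap_extend)
            assert hit.dp_score == pytest.approx(expected, abs=1e-9)

    def test_perfect_match_closed_form(self):
        # one-hot copy of the target, all unpaired, all reactivities above
        # r_c: every site scores alpha*1 + beta*m_match with no gaps
        prof = Profile.from_consensus("ACGU")
        track = ReactivityTrack(np.full(4, 0.9), np.ones(4, bool))
        params = AlignParams(alpha=0.7, beta=2.6)
        hit = align(prof, "ACGU", track, params)
        assert hit.dp_score == pytest.approx(4 * (0.7 + 2.6 * 2.0))  # 23.6
        assert hit.aligned_pairs == [(0, 0), (1, 1), (2, 2), (3, 3)]


class TestReductions:
    def test_alpha_zero_equals_all_undefined(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            prof, target, track, params = random_instance(rng, "simplified")
            p_a0 = AlignParams(
                alpha=0.0, beta=params.beta, gap_open=params.gap_open,
                gap_extend=params.gap_extend, scoring=params.scoring,
                use_consistency=False,
            )
            p_full = AlignParams(
                alpha=params.alpha, beta=params.beta, gap_open=params.gap_open,
                gap_extend=params.gap_extend, scoring=params.scoring,
                use_consistency=False,
            )
            blank = ReactivityTrack.undefined(len(target))
            s1 = align(prof, target, track, p_a0).dp_score
            s2 = align(prof, target, blank, p_full).dp_score
            assert s1 == pytest.approx(s2, abs=1e-12)
            # both equal the sequence-only brute-force oracle
            mm = match_matrix(prof, target, blank, p_full)
            expected = brute_force_semiglobal(mm, params.gap_open, params.gap_extend)
            assert s1 == pytest.approx(expected, abs=1e-9)

    def test_free_target_prefix(self, hairpin_profile, default_params):
        rng = np.random.default_rng(5)
        target = hairpin_profile.consensus()
        base = align(hairpin_profile, target, None, default_params).dp_score
        padded = random_target(rng, 17) + target
        assert align(hairpin_profile, padded, None, default_params).dp_score >= base


class TestConsistency:
    def test_no_consensus_pairs_scores_zero(self, default_params):
        prof = Profile.from_consensus("ACGU")
        hit = align(prof, "ACGU", None, default_params)
        assert hit.consistency_score == 0.0

    def test_canonical_pair_earns_bonus(self, default_params):
        prof = Profile.from_consensus("GAAC", "<..>")
        hit = align(prof, "GAAC", None, default_params)
        assert hit.consistency_score == 1.0
        assert hit.combined_score == hit.dp_score + 1.0

    def test_non_canonical_pair_earns_nothing(self, default_params):
        prof = Profile.from_consensus("GAAC", "<..>")
        hit = align(prof, "GAAG", None, default_params)
        assert hit.consistency_score == 0.0

    def test_bonus_monotonicity_and_decomposition(self, family_profile):
        rng = np.random.default_rng(9)
        target = family_profile.consensus()
        prev_combined = -np.inf
        base_dp = None
        for bonus in (0.0, 0.5, 1.0, 2.0):
            params = AlignParams(consistency_bonus=bonus)
            hit = align(family_profile, target, None, params)
            if base_dp is None:
                base_dp = hit.dp_score
            assert hit.dp_score == base_dp  # bonus never changes the DP
            assert hit.combined_score >= prev_combined
            prev_combined = hit.combined_score
            # decomposition: an integer multiple of the bonus
            if bonus > 0:
                mult = (hit.combined_score - hit.dp_score) / bonus
                assert mult == pytest.approx(round(mult), abs=1e-9)


class TestScan:
    def test_two_planted_copies_found(self, hairpin_profile, default_params):
        rng = np.random.default_rng(3)
        consensus = hairpin_profile.consensus()
        target = (
            random_target(rng, 40) + consensus + random_target(rng, 50)
            + consensus + random_target(rng, 40)
        )
        hits = scan(hairpin_profile, target, None, default_params, max_hits=5)
        top2 = sorted((h.target_start, h.target_end) for h in hits[:2])
        assert top2 == [(41, 68), (119, 146)]
        spans = sorted((h.target_start, h.target_end) for h in hits)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 < s2  # non-overlapping

    def test_max_hits_one_equals_single_align(self, hairpin_profile, default_params):
        rng = np.random.default_rng(4)
        target = random_target(rng, 30) + hairpin_profile.consensus() + random_target(rng, 30)
        single = align(hairpin_profile, target, None, default_params)
        hits = scan(hairpin_profile, target, None, default_params, max_hits=1)
        assert len(hits) == 1
        assert hits[0].combined_score == single.combined_score
        assert (hits[0].target_start, hits[0].target_end) == (
            single.target_start, single.target_end,
        )

    def test_empty_inputs_are_fatal(self, hairpin_profile, default_params):
        with pytest.raises(ValueError):
            align(hairpin_profile, "", None, default_params)
        empty = Profile(np.zeros((0, 6)), np.zeros(0, dtype=np.int8))
        with pytest.raises(ValueError):
            align(empty, "ACGU", None, default_params)


def test_determinism_of_align(hairpin_profile, default_params):
    rng = np.random.default_rng(12)
    target = random_target(rng, 120)
    vals = rng.uniform(0, 2, 120)
    track = ReactivityTrack(vals, np.ones(120, bool))
    h1 = align(hairpin_profile, target, track, default_params)
    h2 = align(hairpin_profile, target, track, default_params)
    assert (h1.dp_score, h1.target_start, h1.target_end, h1.aligned_pairs) == (
        h2.dp_score, h2.target_start, h2.target_end, h2.aligned_pairs,
    )
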