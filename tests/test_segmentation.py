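"""Entropy, split divergence, the Monte-Carlo null, recursion and the DP oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from segdist.segmentation import (
    NullModelRangeError,
    SegmentationConfig,
    SignificanceModel,
    calibrate_null,
    divergence_profile,
    jsd_split,
    max_split,
    optimal_segmentation_dp,
    p_value,
    segment_sequence,
    shannon_entropy,
    write_segments_bed,
    write_segments_tsv,
)
from segdist.seqio import Contig, CountsIndex, GenomeSequence

from conftest import make_genome, two_block_sequence


class TestShannonEntropy:
    @pytest.mark.parametrize(
        "freqs,expected",
        [((.25, .25, .25, .25), 2.0), ((1, 0, 0, 0), 0.0), ((.5, .5, 0, 0), 1.0)],
    )
    def test_known_values(self, freqs, expected):
        assert shannon_entropy(freqs) == pytest.approx(expected)

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            shannon_entropy((0.5, 0.6))
        with pytest.raises(ValueError):
            shannon_entropy((-0.1, 1.1))


class TestJsdSplit:
    def test_disjoint_two_letter_halves_is_one_bit(self):
        assert jsd_split([4, 0, 0, 0], [0, 0, 0, 4]) == pytest.approx(1.0)

    def test_identical_frequencies_give_zero(self):
        assert jsd_split([2, 2, 2, 2], [5, 5, 5, 5]) == pytest.approx(0.0)

    def test_hand_evaluated_mixture(self):
        # flanks AAAT vs ATTT: H(S)=1, each flank H(0.75, 0.25)=0.811278
        assert jsd_split([3, 0, 0, 1], [1, 0, 0, 3]) == pytest.approx(0.188722, abs=1e-6)

    def test_empty_side_is_error(self):
        with pytest.raises(ValueError):
            jsd_split([0, 0, 0, 0], [1, 0, 0, 0])

    @given(st.lists(st.integers(0, 50), min_size=4, max_size=4),
           st.lists(st.integers(0, 50), min_size=4, max_size=4))
    @settings(max_examples=100, deadline=None)
    def test_symmetric_and_bounded(self, left, right):
        if sum(left) == 0 or sum(right) == 0:
            return
        d = jsd_split(left, right)
        assert d == pytest.approx(jsd_split(right, left))
        assert 0.0 <= d <= 2.0 + 1e-12  # log2(4)


class TestDivergenceProfile:
    def test_two_block_profile_peaks_at_boundary(self):
        idx = CountsIndex(make_genome("AAAATTTT"))
        pos, d = divergence_profile(idx, "c1")
        cand = max_split(pos, d)
        assert (cand.position, cand.divergence) == (4, pytest.approx(1.0))

    def test_constant_sequence_is_flat_zero(self):
        idx = CountsIndex(make_genome("AAAAAAAA"))
        _, d = divergence_profile(idx, "c1")
        assert np.allclose(d, 0.0)

    def test_equals_brute_force_recomputation(self):
        rng = np.random.default_rng(1)
        symbols = "".join(rng.choice(list("ACGT"), size=1000))
        idx = CountsIndex(make_genome(symbols))
        pos, d = divergence_profile(idx, "c1")
        for i in rng.choice(len(pos), size=60, replace=False):
            cut = pos[i]
            left = [symbols.count(b, 0, cut) for b in "ACGT"]
            right = [symbols.count(b, cut, 1000) for b in "ACGT"]
            assert d[i] == pytest.approx(jsd_split(left, right), abs=1e-12)

    def test_min_segment_length_restricts_cuts(self):
        idx = CountsIndex(make_genome("ACGTACGTACGT"))
        pos, _ = divergence_profile(idx, "c1", min_segment_length=3)
        assert pos[0] == 3 and pos[-1] == 9

    def test_too_short_range_gives_empty_profile(self):
        idx = CountsIndex(make_genome("AC"))
        pos, d = divergence_profile(idx, "c1", 0, 1)
        assert len(pos) == 0


class TestMaxSplit:
    def test_leftmost_on_all_zero_profile(self):
        pos = np.arange(1, 8)
        cand = max_split(pos, np.zeros(7))
        assert (cand.position, cand.divergence) == (1, 0.0)

    def test_leftmost_on_tied_maxima(self):
        pos = np.arange(1, 8)
        d = np.array([0, 0, 5, 0, 5, 0, 0], dtype=float)
        assert max_split(pos, d).position == 3

    def test_empty_profile_is_error(self):
        with pytest.raises(ValueError):
            max_split(np.empty(0, dtype=int), np.empty(0))


class TestCalibrateNull:
    def test_same_seed_identical_table(self):
        a = calibrate_null([256, 512], n_sims=200, seed=5)
        b = calibrate_null([512, 256], n_sims=200, seed=5)
        for n in (256, 512):
            assert np.array_equal(a.samples[n], b.samples[n])

    def test_p_value_self_consistency_at_own_quantiles(self, null_small):
        m = null_small
        q95 = m.quantile(0.95, 1024)
        assert m.p_value(q95, 1024) == pytest.approx(0.05, abs=0.01)
        q50 = m.quantile(0.5, 1024)
        assert m.p_value(q50, 1024) == pytest.approx(0.5, abs=0.05)

    def test_quantiles_decrease_with_length(self, null_small):
        qs = [null_small.quantile(0.95, n) for n in (64, 256, 1024, 4096)]
        assert all(a > b for a, b in zip(qs, qs[1:]))

    def test_p_value_monotone_in_divergence(self, null_small):
        grid = np.linspace(0, 2, 50)
        ps = [null_small.p_value(d, 700) for d in grid]  # interpolated length
        assert all(a >= b for a, b in zip(ps, ps[1:]))
        assert ps[0] == 1.0 and ps[-1] == 0.0

    def test_extreme_divergences(self, null_small):
        assert p_value(0.0, 512, null_small) == 1.0
        assert p_value(2.0, 512, null_small) == 0.0

    def test_length_outside_hull_is_explicit_error(self, null_small):
        with pytest.raises(NullModelRangeError):
            null_small.p_value(0.1, 10**7)

    def test_grid_validation(self):
        with pytest.raises(ValueError):
            calibrate_null([2], n_sims=100)
        with pytest.raises(ValueError):
            calibrate_null([], n_sims=100)

    def test_save_load_round_trip(self, tmp_path, null_small):
        path = tmp_path / "null.tsv"
        null_small.save(path)
        loaded = SignificanceModel.load(path)
        assert loaded.k == null_small.k
        assert loaded.grid == null_small.grid
        for n in null_small.grid:
            assert np.allclose(loaded.samples[n], null_small.samples[n])


class TestSegmentSequence:
    def test_two_block_sequence_recovers_boundary(self, null_1m):
        rng = np.random.default_rng(7)
        g = make_genome(two_block_sequence(rng, 0.35, 0.55, 50_000))
        res = segment_sequence(g, SegmentationConfig(), null_1m)
        res.validate()
        assert res.m >= 2
        boundaries = sorted(s.end for s in res.segments)[:-1]
        assert any(abs(b - 50_000) <= 500 for b in boundaries)

    def test_short_contig_single_segment(self, null_small):
        g = make_genome("ACG")
        cfg = SegmentationConfig(min_segment_length=2)
        res = segment_sequence(g, cfg, null_small)
        assert res.m == 1 and res.segments[0].counts == (1, 1, 1, 0)

    def test_determinism(self, null_small):
        rng = np.random.default_rng(3)
        g = make_genome(two_block_sequence(rng, 0.3, 0.6, 2000))
        cfg = SegmentationConfig()
        r1 = segment_sequence(g, cfg, null_small)
        r2 = segment_sequence(g, cfg, null_small)
        assert [(s.start, s.end) for s in r1.segments] == \
            [(s.start, s.end) for s in r2.segments]

    def test_binary_grouping_mode(self, null_small):
        binary_null = calibrate_null([8, 64, 512, 4096], k=2, n_sims=300, seed=2)
        rng = np.random.default_rng(4)
        g = make_genome(two_block_sequence(rng, 0.30, 0.62, 2000))
        res = segment_sequence(g, SegmentationConfig(alphabet="SW"), binary_null)
        res.validate()
        assert res.m >= 2

    def test_alphabet_mismatch_rejected(self, null_small):
        g = make_genome("ACGTACGT")
        with pytest.raises(ValueError):
            segment_sequence(g, SegmentationConfig(alphabet="SW"), null_small)

    def test_accepted_cuts_were_significant(self, null_small):
        """Every reported divergence is within the alphabet bound."""
        rng = np.random.default_rng(8)
        g = make_genome(two_block_sequence(rng, 0.3, 0.6, 2000))
        res = segment_sequence(g, SegmentationConfig(), null_small)
        res.validate()
        for seg in res.segments:
            assert sum(seg.counts) == seg.end - seg.start

    def test_writers_emit_wellformed_files(self, tmp_path, null_small):
        rng = np.random.default_rng(9)
        g = make_genome(two_block_sequence(rng, 0.3, 0.6, 1000))
        res = segment_sequence(g, SegmentationConfig(), null_small)
        bed, tsv = tmp_path / "s.bed", tmp_path / "s.tsv"
        write_segments_bed(res, g, bed)
        write_segments_tsv(res, tsv)
        lines = bed.read_text().strip().split("\n")
        assert len(lines) == res.m
        first = lines[0].split("\t")
        assert first[0] == "c1" and int(first[1]) == 0
        assert tsv.read_text().startswith("#taxon=toy")


class TestSegmentationConfig:
    def test_significance_relation_to_p0(self):
        cfg = SegmentationConfig(significance=0.9)
        assert cfg.p0 == pytest.approx(0.1)

    def test_invalid_values(self):
        with pytest.raises(ValueError):
            SegmentationConfig(significance=1.0)
        with pytest.raises(ValueError):
            SegmentationConfig(alphabet="XY")
        with pytest.raises(ValueError):
            SegmentationConfig(min_segment_length=0)


class TestOptimalDP:
    def test_one_cut_on_two_blocks(self):
        segments, obj = optimal_segmentation_dp("AAAATTTT", 1)
        assert segments == [(0, 4), (4, 8)]
        assert obj == pytest.approx(1.0)

    def test_objective_nesting_monotone_in_cuts(self):
        rng = np.random.default_rng(2)
        seq = "".join(rng.choice(list("ACGT"), size=400))
        objs = [optimal_segmentation_dp(seq, c)[1] for c in range(4)]
        assert all(b >= a - 1e-12 for a, b in zip(objs, objs[1:]))

    def test_cut_count_validation(self):
        with pytest.raises(ValueError):
            optimal_segmentation_dp("ACGT", 4)

    def test_heuristic_first_cut_equals_dp_optimum_small(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            symbols = "".join(rng.choice(list("ACGT"), size=500))
            idx = CountsIndex(make_genome(symbols))
            cand = max_split(*divergence_profile(idx, "c1"))
            (seg1, seg2), _ = optimal_segmentation_dp(symbols, 1)
            assert seg1[1] == cand.position
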