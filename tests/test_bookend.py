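import numpy as np
import pytest

from _reference import enumerated_cooccurrence_pvalue
from exomotif.bookend import (
    BookendParams,
    bookend_all,
    cooccurrence_pvalue,
    count_cooccurrence,
    merge_pair,
)
from exomotif.graph_clique import PotentialMotif
from exomotif.io_formats import PeakRecord
from exomotif.weighting import WeightedPeakSet, build_strand_matrix


def make_matrix(m=4, n=60, seed=0):
    rng = np.random.default_rng(seed)
    records = [
        PeakRecord(id=f"p{i}", sequence="".join(rng.choice(list("ACGT"), n)))
        for i in range(m)
    ]
    return build_strand_matrix(WeightedPeakSet.from_records(records, mode="basic"))


def motif(instances, l=14):
    return PotentialMotif(instances=tuple(instances), l=l, score=1.0)


class TestCountCooccurrence:
    def test_windowed_pair_with_overlap(self):
        mat = make_matrix()
        c_i = motif([(0, 0)])
        c_j = motif([(0, 8)])
        o, pairs = count_cooccurrence(c_i, c_j, mat, d=25)
        assert o == 1 and pairs[0][2] == 6  # spans 0-14 and 8-22 overlap by 6

    def test_different_peaks_not_counted(self):
        mat = make_matrix()
        o, _ = count_cooccurrence(motif([(0, 0)]), motif([(2, 8)]), mat, d=25)
        assert o == 0

    def test_span_exceeding_window_not_counted(self):
        mat = make_matrix()
        o, _ = count_cooccurrence(motif([(0, 0)]), motif([(0, 40)]), mat, d=25)
        assert o == 0  # joint span 54 > 25

    def test_opposite_strand_instances_counted(self):
        mat = make_matrix(n=60)
        # row 1 is the revcomp strand of peak 0; start 38 there maps to
        # forward interval [8, 22)
        o, pairs = count_cooccurrence(motif([(0, 0)]), motif([(1, 60 - 22)]), mat, d=25)
        assert o == 1 and pairs[0][2] == 6

    def test_one_to_one_nearest_matching(self):
        mat = make_matrix()
        # two c_j instances compete for one c_i instance: only one pair
        o, pairs = count_cooccurrence(motif([(0, 8)]), motif([(0, 0), (0, 10)]), mat, d=40)
        assert o == 1
        # the closer instance (start 10, span 16) wins over start 0 (span 22)
        assert pairs[0][1] == (0, 10, 14)


class TestCooccurrencePvalue:
    def test_zero_count_full_tail(self):
        assert cooccurrence_pvalue(0, 5, 3, d=25, m=10, n=200) == pytest.approx(1.0)

    def test_hand_computed_binomial(self):
        # p = d*n_i/(m*n) = 10*2/(2*100) = 0.1; P(X>=2 | n=2) = 0.01
        assert cooccurrence_pvalue(2, 2, 2, d=10, m=2, n=100) == pytest.approx(0.01)

    def test_swaps_to_keep_ni_largest(self):
        a = cooccurrence_pvalue(2, 2, 8, d=10, m=4, n=100)
        b = cooccurrence_pvalue(2, 8, 2, d=10, m=4, n=100)
        assert a == pytest.approx(b)

    def test_clamped_probability(self):
        # d*n_i >> m*n would give p > 1; clamp keeps a valid value
        assert cooccurrence_pvalue(3, 50, 3, d=100, m=2, n=20) == pytest.approx(1.0)

    def test_error_on_count_exceeding_nj(self):
        with pytest.raises(ValueError):
            cooccurrence_pvalue(4, 5, 3, d=25, m=10, n=200)

    @pytest.mark.parametrize("n_j", [1, 3, 6, 9, 12])
    def test_matches_outcome_enumeration(self, n_j):
        d, m, n = 25, 10, 180.0
        n_i = n_j + 2
        p = d * n_i / (m * n)
        for o in range(n_j + 1):
            assert cooccurrence_pvalue(o, n_i, n_j, d, m, n) == pytest.approx(
                enumerated_cooccurrence_pvalue(o, n_j, p), abs=1e-10
            )

    def test_monotone_decreasing_in_o(self):
        vals = [cooccurrence_pvalue(o, 8, 8, 25, 10, 200.0) for o in range(9)]
        assert all(b <= a + 1e-15 for a, b in zip(vals, vals[1:]))


class TestMergePair:
    def _pair_with_overlaps(self, offsets, m=12, n=60):
        """Motifs whose instance pairs overlap by 14 - offset on each peak."""
        mat = make_matrix(m=m, n=n, seed=1)
        c_i = motif([(2 * k, 0) for k in range(len(offsets))])
        c_j = motif([(2 * k, off) for k, off in enumerate(offsets)])
        return c_i, c_j, mat

    def test_modal_overlap_and_width(self):
        c_i, c_j, mat = self._pair_with_overlaps([8, 8, 8, 10])
        res = merge_pair(c_i, c_j, mat, BookendParams())
        assert res.merged and res.l_o == 6 and res.l_x == 22
        assert all(width == 22 for _, _, width in res.instances)

    def test_tie_prefers_larger_overlap(self):
        c_i, c_j, mat = self._pair_with_overlaps([10, 10, 8, 8])
        res = merge_pair(c_i, c_j, mat, BookendParams())
        assert res.merged and res.l_o == 6  # overlaps {4,4,6,6} -> 6

    def test_insignificant_pair_not_merged(self):
        mat = make_matrix(m=12, n=60, seed=2)
        c_i = motif([(0, 0)])
        c_j = motif([(0, 8)])
        # one co-occurring pair among many possible placements: P >= 0.05
        res = merge_pair(c_i, c_j, mat, BookendParams(p_cutoff=0.01))
        assert not res.merged and res.instances == ()

    def test_nonpositive_modal_overlap_rejects_merge(self):
        # adjacent but non-overlapping instances count toward o_ij but
        # cannot define a merged width
        c_i, c_j, mat = self._pair_with_overlaps([14, 14, 14, 14], m=8)
        res = merge_pair(c_i, c_j, mat, BookendParams(d=30))
        assert res.o_ij == 4 and not res.merged

    def test_unequal_widths_use_general_formula(self):
        # widths 14 and 12 overlapping by 6 fuse to 14 + 12 - 6 = 20
        mat = make_matrix(m=12, n=60, seed=6)
        c_i = motif([(2 * k, 0) for k in range(4)], l=14)
        c_j = motif([(2 * k, 8) for k in range(4)], l=12)
        res = merge_pair(c_i, c_j, mat, BookendParams())
        assert res.merged and res.l_o == 6 and res.l_x == 20


class TestBookendAll:
    def test_single_motif_passthrough(self):
        mat = make_matrix()
        seeds = bookend_all([motif([(0, 0), (2, 5)])], mat, BookendParams())
        assert len(seeds) == 1 and seeds[0].width == 14 and seeds[0].l_o == 14

    def test_disjoint_sequence_sets_never_merge(self):
        mat = make_matrix(m=8, n=60, seed=3)
        c_i = motif([(0, 3), (2, 9), (4, 20)])
        c_j = motif([(8, 3), (10, 9), (12, 20)])
        seeds = bookend_all([c_i, c_j], mat, BookendParams())
        assert len(seeds) == 2 and all(s.width == 14 for s in seeds)

    def test_each_motif_merges_at_most_once(self):
        mat = make_matrix(m=12, n=60, seed=4)
        a = motif([(2 * k, 0) for k in range(6)])
        b = motif([(2 * k, 8) for k in range(6)])
        c = motif([(2 * k, 10) for k in range(6)])
        seeds = bookend_all([a, b, c], mat, BookendParams())
        merged = [s for s in seeds if s.width != 14]
        assert len(merged) == 1  # most significant pair wins, third passes
        assert len(seeds) == 2

    def test_merged_width_bounds(self):
        mat = make_matrix(m=12, n=60, seed=5)
        a = motif([(2 * k, 0) for k in range(6)])
        b = motif([(2 * k, 8) for k in range(6)])
        seeds = bookend_all([a, b], mat, BookendParams())
        for s in seeds:
            assert 14 <= s.width < 28
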