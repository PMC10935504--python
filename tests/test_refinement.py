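import math

import numpy as np
import pytest

from exomotif.bookend import MotifSeed
from exomotif.io_formats import PeakRecord
from exomotif.refinement import (
    build_pwm,
    estimate_background,
    expand_instances,
    instance_sequence,
    match_score,
    model_from_seed,
)
from exomotif.weighting import WeightedPeakSet, build_strand_matrix


def matrix_from(seqs, covs=None, mode="cov"):
    records = []
    for i, s in enumerate(seqs):
        cov = None if covs is None else np.asarray(covs[i], dtype=float)
        records.append(PeakRecord(id=f"p{i}", sequence=s, coverage=cov))
    peaks = WeightedPeakSet.from_records(records, mode=mode)
    mat = build_strand_matrix(peaks)
    return mat, mat.row_normalized()


class TestEstimateBackground:
    def test_uniform_genome(self):
        np.testing.assert_allclose(estimate_background(["AACCGGTT"]), 0.25)

    def test_zero_guard_lifts_and_renormalises(self):
        q = estimate_background(["AAAA"])
        assert q[0] == pytest.approx(1.0, abs=1e-5)
        assert (q > 0).all() and q.sum() == pytest.approx(1.0)

    def test_n_excluded(self):
        np.testing.assert_allclose(estimate_background(["ACNNGT"]), 0.25)

    def test_all_n_error(self):
        with pytest.raises(ValueError):
            estimate_background(["NNNN"])


class TestBuildPwm:
    def test_uniform_counts_zero_log_odds(self):
        mat, _ = matrix_from(["ACGT", "CGTA", "GTAC", "TACG"])
        model = build_pwm([(2 * i, 0, 4) for i in range(4)], mat, np.full(4, 0.25))
        np.testing.assert_allclose(model.pwm, 0.0, atol=1e-12)

    def test_pseudocount_arithmetic(self):
        # counts {A:3, C:1}: p(A) = 3.25/5 = 0.65... with pseudo=1 split
        mat, _ = matrix_from(["A", "A", "A", "C"])
        model = build_pwm([(2 * i, 0, 1) for i in range(4)], mat, np.full(4, 0.25))
        assert model.frequencies[0, 0] == pytest.approx(3.25 / 5)
        assert model.pwm[0, 0] == pytest.approx(math.log2((3.25 / 5) / 0.25))

    def test_consensus_matches_identical_instances(self):
        mat, _ = matrix_from(["ACGTA"] * 10)
        model = build_pwm([(2 * i, 0, 5) for i in range(10)], mat, np.full(4, 0.25))
        assert model.consensus == "ACGTA"

    def test_n_spreads_evenly(self):
        mat, _ = matrix_from(["ANT", "AAT"])
        model = build_pwm([(0, 0, 3), (2, 0, 3)], mat, np.full(4, 0.25))
        np.testing.assert_allclose(model.counts[:, 1], [1.25, 0.25, 0.25, 0.25])

    def test_length_mismatch_error(self):
        mat, _ = matrix_from(["ACGTA", "ACG"])
        with pytest.raises(ValueError):
            build_pwm([(0, 0, 5), (2, 0, 5)], mat, np.full(4, 0.25))

    def test_rebuild_idempotent(self):
        mat, _ = matrix_from(["ACGTACGT", "ACGAACGT", "TCGTACGA"])
        insts = [(0, 1, 6), (2, 1, 6), (4, 0, 6)]
        q = np.full(4, 0.25)
        a = build_pwm(insts, mat, q)
        b = build_pwm(a.instances, mat, q)
        np.testing.assert_allclose(a.pwm, b.pwm)


class TestMatchScore:
    def test_basic_mode_reduces_to_log_odds_sum(self):
        mat, mh = matrix_from(["ACGTACGT"] * 3, mode="basic")
        model = build_pwm([(2 * i, 0, 4) for i in range(3)], mat, np.full(4, 0.25))
        s = match_score((0, 2), model, mat, mh)
        code_sum = sum(
            model.pwm["ACGT".index(b), j]
            for j, b in enumerate(mat.sequences[0][2:6])
        )
        assert s == pytest.approx(code_sum)

    def test_consensus_segment_is_row_argmax(self):
        seqs = ["TTTTACGTACTTTT"] * 4
        mat, mh = matrix_from(seqs, mode="basic")
        model = build_pwm([(2 * i, 4, 6) for i in range(4)], mat, np.full(4, 0.25))
        scores = [match_score((0, j), model, mat, mh) for j in range(14 - 6 + 1)]
        assert int(np.argmax(scores)) == 4

    def test_hand_computed_weighted_toy(self):
        # two identical instances, explicit coverage row, l_x=4, t=2
        covs = [[1, 2, 4, 8, 4, 2, 1, 1], [1, 2, 4, 8, 4, 2, 1, 1]]
        mat, mh = matrix_from(["ACGTACGT", "ACGTACGT"], covs)
        model = build_pwm([(0, 0, 4), (2, 0, 4)], mat, np.full(4, 0.25))
        s = match_score((0, 1), model, mat, mh)
        # coverage factor: windows [max(0,-1),1] and [1, 1+4+2] of mh row 0
        row = mh[0]
        factor = 0.5 * (row[0:2].max() + row[1:8].max())
        logodds = sum(
            model.pwm["ACGT".index(b), j] for j, b in enumerate("CGTA")
        )
        assert s == pytest.approx(factor * logodds)

    def test_out_of_bounds_error(self):
        mat, mh = matrix_from(["ACGTACGT"] * 2, mode="basic")
        model = build_pwm([(0, 0, 4), (2, 0, 4)], mat, np.full(4, 0.25))
        with pytest.raises(ValueError):
            match_score((0, 6), model, mat, mh)


class TestExpandInstances:
    def _planted(self):
        core = "ACGTGCAT"
        rng = np.random.default_rng(0)
        seqs = []
        for i in range(6):
            flank = "".join(rng.choice(list("ACGT"), 30))
            seqs.append(flank[:10] + core + flank[10:])
        return matrix_from(seqs, mode="basic"), core

    def test_fixed_point_when_nothing_beats_threshold(self):
        (mat, mh), core = self._planted()
        insts = [(2 * i, 10, 8) for i in range(6)]
        model = build_pwm(insts, mat, np.full(4, 0.25))
        out = expand_instances(model, mat, mh)
        # all planted copies already included; nothing below min survives
        assert set(model.instances) <= set(out.instances)

    def test_recovers_missed_planted_site(self):
        core = "ACGTGCAT"
        degraded = "ACGTGCAA"  # one mismatch lowers the weakest score
        rng = np.random.default_rng(0)
        seqs = []
        for i in range(6):
            flank = "".join(rng.choice(list("ACGT"), 30))
            insert = degraded if i == 0 else core
            seqs.append(flank[:10] + insert + flank[10:])
        (mat, mh) = matrix_from(seqs, mode="basic")
        # model built without the exact-copy site on peak 5
        insts = [(2 * i, 10, 8) for i in range(5)]
        model = build_pwm(insts, mat, np.full(4, 0.25))
        out = expand_instances(model, mat, mh)
        rows = {row for row, start, _ in out.instances if start == 10 and row % 2 == 0}
        assert 10 in rows  # the held-out peak's exact site beats the degraded one

    def test_expansion_never_removes_instances(self):
        (mat, mh), _ = self._planted()
        insts = [(2 * i, 10, 8) for i in range(4)]
        model = build_pwm(insts, mat, np.full(4, 0.25))
        out = expand_instances(model, mat, mh, iterations=3)
        assert set(insts) <= set(out.instances)
        assert out.nsites >= model.nsites

    def test_seed_model_l_o_defaults_to_width(self):
        mat, _ = matrix_from(["ACGTACGTACGTACGTAC"] * 3, mode="basic")
        seed = MotifSeed(
            instances=tuple((2 * i, 0, 14) for i in range(3)),
            width=14, l_o=14, source_l=14,
        )
        model = model_from_seed(seed, mat, np.full(4, 0.25))
        assert model.l_o == 14 and model.width == 14
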