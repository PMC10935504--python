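"""Two-stage weighted segment alignment.

Every pair of l-segments drawn from distinct peaks (all four strand
combinations) is scored by the upper-tail binomial significance of its
identity count,

    f(k, l) = -log10( sum_{j=k}^{l} C(l,j) 0.25^j 0.75^(l-j) ),

i.e. the chance of seeing at least k matches between unrelated segments
under a uniform background. Stage 1 weights f by the coverage at the two
segment starts, f' = f * (w_ij + w_pq), and accumulates per-position
support counts M1 for pairs that either exceed the f threshold or rank in
the top alpha of f' within their row pair. Stage 2 repeats the sweep with
f' = f * max over a +/-2 bp neighbourhood of (M1_i + M1_p), exploiting
that true motif instances concentrate support at proximal offsets; the
resulting M2 is row-normalised and floored by the row-normalised coverage
matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import maximum_filter1d
from scipy.special import gammaln, logsumexp

from .weighting import StrandCoverageMatrix

log = logging.getLogger(__name__)


@dataclass
class AlignmentParams:
    """Knobs of the two-stage alignment.

    l: segment length (motif seed width). f_threshold: minimum binomial
    significance (-log10 tail probability) for an unconditional support
    increment. alpha: per-row-pair rank cutoff for the weighted score.
    l_range: optional inclusive (lo, hi) sweep of l values.
    """

    l: int = 14
    f_threshold: float = 3.0
    alpha: int = 5
    l_range: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.l < 4:
            raise ValueError("segment length l must be >= 4")
        if self.alpha < 1:
            raise ValueError("alpha must be >= 1")
        if self.f_threshold < 0:
            raise ValueError("f_threshold must be >= 0")
        if self.l_range is not None:
            lo, hi = self.l_range
            if lo < 4 or hi < lo:
                raise ValueError(f"invalid l_range {self.l_range}")

    def l_values(self) -> list[int]:
        if self.l_range is None:
            return [self.l]
        lo, hi = self.l_range
        return list(range(lo, hi + 1))


def count_identities(a: str, b: str) -> int:
    """Number of positions where two equal-length segments agree.

    Positions where either base is N never count as identical.
    """
    if len(a) != len(b):
        raise ValueError(f"segment lengths differ: {len(a)} vs {len(b)}")
    return sum(x == y and x != "N" for x, y in zip(a, b))


def segment_similarity(k: int, l: int) -> float:
    """Binomial upper-tail significance of k identities in l positions.

    Computed in log space (gammaln + logsumexp) so large l cannot
    underflow. f(0, l) = 0 since the full tail sums to 1; f is strictly
    increasing in k.
    """
    if not 0 <= k <= l:
        raise ValueError(f"k={k} outside [0, {l}]")
    return float(similarity_table(l)[k])


_TABLE_CACHE: dict[int, np.ndarray] = {}


def similarity_table(l: int) -> np.ndarray:
    """f(k, l) for all k in 0..l, cached per l."""
    tab = _TABLE_CACHE.get(l)
    if tab is None:
        j = np.arange(l + 1)
        log_terms = (
            gammaln(l + 1)
            - gammaln(j + 1)
            - gammaln(l - j + 1)
            + j * np.log(0.25)
            + (l - j) * np.log(0.75)
        )
        # tail log-prob for each k: logsumexp over terms j >= k
        tail = np.array([logsumexp(log_terms[k:]) for k in range(l + 1)])
        tail[0] = 0.0  # full tail is exactly 1
        tab = -tail / np.log(10.0)
        tab[tab < 0] = 0.0
        _TABLE_CACHE[l] = tab
    return tab


def weighted_similarity_stage1(f: float, w_ij: float, w_pq: float) -> float:
    """Stage-1 coverage weighting: f' = f * (w_ij + w_pq)."""
    return f * (w_ij + w_pq)


def neighborhood_weighted_similarity(
    f: float, m1_rows: list[np.ndarray], row_i: int, pos_j: int, row_p: int, pos_q: int
) -> float:
    """Stage-2 weighting: f times the max of M1_i + M1_p over a +/-2 window.

    The maxima separate over the sum, so each row is maximised
    independently; out-of-range neighbours are skipped.
    """
    a = m1_rows[row_i]
    b = m1_rows[row_p]
    lo_j, hi_j = max(0, pos_j - 2), min(len(a), pos_j + 3)
    lo_q, hi_q = max(0, pos_q - 2), min(len(b), pos_q + 3)
    return f * (a[lo_j:hi_j].max(initial=0.0) + b[lo_q:hi_q].max(initial=0.0))


def eligible_row_pairs(n_rows: int):
    """Unordered strand-row pairs linking two distinct original peaks.

    A peak is never aligned against itself or its own reverse
    complement; all four strand combinations of two distinct peaks are
    eligible. f and f' are symmetric in the pair, so each unordered pair
    is processed once and both endpoints receive increments.
    """
    m = n_rows // 2
    for a in range(m):
        for b in range(a + 1, m):
            for ra in (2 * a, 2 * a + 1):
                for rb in (2 * b, 2 * b + 1):
                    yield ra, rb


def _rank_mask(fprime: np.ndarray, alpha: int) -> np.ndarray:
    """Pairs whose f' ranks in the top alpha (ties at the cutoff included).

    Zero-score pairs carry no alignment signal and never qualify.
    """
    positive = fprime[fprime > 0]
    if positive.size == 0:
        return np.zeros_like(fprime, dtype=bool)
    if positive.size <= alpha:
        return fprime > 0
    cutoff = np.partition(positive, -alpha)[-alpha]
    return fprime >= cutoff


class PairScorer:
    """Caches per-row-pair identity-count matrices across the two stages.

    For rows of lengths n1, n2 the matrix K[j, q] counts identities
    between the l-segments starting at j and q, built from l shifted
    slice-adds of the base-equality matrix (N excluded on both sides).
    """

    def __init__(self, matrix: StrandCoverageMatrix, l: int):
        self.matrix = matrix
        self.l = l
        self._cache: dict[tuple[int, int], np.ndarray] = {}
        for row, code in enumerate(matrix.codes):
            if len(code) < l:
                rec = matrix.peaks.records[row // 2]
                raise ValueError(
                    f"segment length l={l} exceeds sequence {rec.id!r} of length {len(code)}"
                )

    def valid_starts(self, row: int) -> int:
        return self.matrix.row_length(row) - self.l + 1

    def identity_counts(self, r1: int, r2: int) -> np.ndarray:
        key = (r1, r2)
        cached = self._cache.get(key)
        if cached is not None:
            return cached
        c1, c2 = self.matrix.codes[r1], self.matrix.codes[r2]
        eq = (c1[:, None] == c2[None, :]) & (c1[:, None] != 4) & (c2[None, :] != 4)
        j1, j2 = len(c1) - self.l + 1, len(c2) - self.l + 1
        counts = np.zeros((j1, j2), dtype=np.int16)
        for t in range(self.l):
            counts += eq[t : t + j1, t : t + j2]
        counts = counts.astype(np.uint8)
        self._cache[key] = counts
        return counts

    def f_matrix(self, r1: int, r2: int) -> np.ndarray:
        return similarity_table(self.l)[self.identity_counts(r1, r2)]


def first_pass(
    matrix: StrandCoverageMatrix,
    params: AlignmentParams,
    scorer: PairScorer | None = None,
) -> list[np.ndarray]:
    """Stage-1 support counts M1 (one vector of valid starts per row)."""
    scorer = scorer or PairScorer(matrix, params.l)
    m1 = [np.zeros(scorer.valid_starts(r)) for r in range(matrix.n_rows)]
    total = 0
    for r1, r2 in eligible_row_pairs(matrix.n_rows):
        f = scorer.f_matrix(r1, r2)
        w1 = matrix.rows[r1][: f.shape[0]]
        w2 = matrix.rows[r2][: f.shape[1]]
        fprime = f * (w1[:, None] + w2[None, :])
        mask = (f > params.f_threshold) | _rank_mask(fprime, params.alpha)
        m1[r1] += mask.sum(axis=1)
        m1[r2] += mask.sum(axis=0)
        total += int(mask.sum())
    log.debug("stage 1: %d qualifying segment pairs", total)
    return m1


def second_pass(
    matrix: StrandCoverageMatrix,
    m1: list[np.ndarray],
    params: AlignmentParams,
    scorer: PairScorer | None = None,
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Stage-2 combined weights M2 and the row-normalised coverage matrix.

    The increment rule matches stage 1 but scores with the neighbourhood
    form of f'. Afterwards M2 and the coverage matrix are each divided by
    their row maxima (all-zero rows stay zero) and the normalised
    coverage, restricted to valid starts, is added onto M2.
    """
    scorer = scorer or PairScorer(matrix, params.l)
    # window max of M1 over [j-2, j+2]; entries are >= 0 so zero padding
    # equals truncation at row bounds
    wmax = [maximum_filter1d(v, size=5, mode="constant", cval=0.0) if v.size else v
            for v in m1]
    m2 = [np.zeros(scorer.valid_starts(r)) for r in range(matrix.n_rows)]
    total = 0
    for r1, r2 in eligible_row_pairs(matrix.n_rows):
        f = scorer.f_matrix(r1, r2)
        fprime = f * (wmax[r1][:, None] + wmax[r2][None, :])
        mask = (f > params.f_threshold) | _rank_mask(fprime, params.alpha)
        m2[r1] += mask.sum(axis=1)
        m2[r2] += mask.sum(axis=0)
        total += int(mask.sum())
    log.debug("stage 2: %d qualifying segment pairs", total)
    mh_norm = matrix.row_normalized()
    out = []
    for r, row in enumerate(m2):
        top = row.max(initial=0.0)
        normed = row / top if top > 0 else row
        out.append(normed + mh_norm[r][: len(row)])
    return out, mh_norm
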