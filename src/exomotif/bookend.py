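"""Motif width optimisation by the bookend co-occurrence test.

Two potential motifs whose instances repeatedly land within a short
window of one another on the same peaks are likely two halves of a single
wider motif. For motifs c_i and c_j with n_i >= n_j instances, the count
o_ij of one-to-one nearest instance pairs that fit in a window of d
consecutive bp is tested against the binomial null

    P(o_ij) = sum_{k=o_ij}^{n_j} C(n_j, k) p^k (1-p)^(n_j-k),
    p = (d * n_i) / (m * n),

where m is the peak count and n the (mean) peak length. Significant
pairs merge: instance pairs whose nucleotide overlap equals the modal
overlap l_o are fused into union spans of width l_x = 2l - l_o.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import binom

from .graph_clique import PotentialMotif
from .weighting import StrandCoverageMatrix

log = logging.getLogger(__name__)


@dataclass
class BookendParams:
    d: int = 25
    p_cutoff: float = 0.05
    max_rounds: int = 1

    def __post_init__(self) -> None:
        if self.d < 1:
            raise ValueError("window width d must be >= 1")
        if not 0 < self.p_cutoff < 1:
            raise ValueError("p_cutoff must lie in (0, 1)")
        if self.max_rounds < 1:
            raise ValueError("max_rounds must be >= 1")


@dataclass
class MotifSeed:
    """A width-resolved instance set feeding the PWM expansion stage.

    Instances are (row, start, width) on strand rows. For unmerged seeds
    l_o equals the width itself.
    """

    instances: tuple[tuple[int, int, int], ...]
    width: int
    l_o: int
    source_l: int

    @property
    def size(self) -> int:
        return len(self.instances)


@dataclass
class MergeResult:
    merged: bool
    o_ij: int
    p_value: float
    l_o: int | None
    instances: tuple[tuple[int, int, int], ...]
    l_x: int | None


def _instances3(motif) -> tuple[tuple[int, int, int], ...]:
    """(row, start, width) triples from a PotentialMotif or MotifSeed."""
    if isinstance(motif, PotentialMotif):
        return tuple((r, s, motif.l) for r, s in motif.instances)
    return tuple(motif.instances)


def _width_of(motif) -> int:
    return motif.l if isinstance(motif, PotentialMotif) else motif.width


def count_cooccurrence(c_i, c_j, matrix: StrandCoverageMatrix, d: int):
    """Count windowed instance pairs and record their signed overlaps.

    Instances (on either strand) are mapped to forward coordinates; a
    pair counts when both lie on the same peak and their joint span fits
    in d consecutive bp. Matching is one-to-one nearest (smallest joint
    span first) so a dense cluster cannot inflate the count. Returns the
    count and a list of ((row, start, w)_i, (row, start, w)_j, overlap).
    """
    if d < max(_width_of(c_i), _width_of(c_j)):
        log.warning("window d=%d is narrower than the motif length", d)
    by_seq_j: dict[int, list[tuple[int, int, tuple[int, int, int]]]] = {}
    for row, start, w in _instances3(c_j):
        seq, s, e = matrix.to_forward_span(row, start, w)
        by_seq_j.setdefault(seq, []).append((s, e, (row, start, w)))
    candidates = []
    for row, start, w in _instances3(c_i):
        seq, s_i, e_i = matrix.to_forward_span(row, start, w)
        for s_j, e_j, vj in by_seq_j.get(seq, []):
            span = max(e_i, e_j) - min(s_i, s_j)
            if span <= d:
                overlap = min(e_i, e_j) - max(s_i, s_j)
                candidates.append((span, (row, start, w), vj, overlap))
    candidates.sort(key=lambda c: (c[0], c[1], c[2]))
    taken_i: set = set()
    taken_j: set = set()
    pairs = []
    for span, vi, vj, overlap in candidates:
        if vi in taken_i or vj in taken_j:
            continue
        taken_i.add(vi)
        taken_j.add(vj)
        pairs.append((vi, vj, overlap))
    return len(pairs), pairs


def cooccurrence_pvalue(o_ij: int, n_i: int, n_j: int, d: int, m: int, n: float) -> float:
    """Binomial upper-tail probability of observing >= o_ij windowed pairs.

    n_i >= n_j is enforced by swapping; p = d*n_i/(m*n) is clamped into
    (0, 1]. o_ij = 0 gives P = 1 (the full tail).
    """
    if n_i < n_j:
        n_i, n_j = n_j, n_i
    if not 0 <= o_ij <= n_j:
        raise ValueError(f"o_ij={o_ij} outside [0, n_j={n_j}]")
    p = min(1.0, (d * n_i) / (m * n))
    return float(binom.sf(o_ij - 1, n_j, p))


def merge_pair(c_i, c_j, matrix: StrandCoverageMatrix, params: BookendParams) -> MergeResult:
    """Test one motif pair for merging and build the merged instance set.

    On significance, l_o is the mode of the strictly positive recorded
    overlaps (ties favour the larger overlap); pairs overlapping by
    exactly l_o are fused into their union span — width 2l - l_o when
    both motifs have segment length l, and w_i + w_j - l_o in general —
    with strand and row taken from the c_i member. Pairs never merge
    when the modal overlap would be <= 0.
    """
    m = matrix.peaks.m
    n = matrix.peaks.mean_length
    o_ij, pairs = count_cooccurrence(c_i, c_j, matrix, params.d)
    n_i = len(_instances3(c_i))
    n_j = len(_instances3(c_j))
    p_value = cooccurrence_pvalue(o_ij, n_i, n_j, params.d, m, n)
    no_merge = MergeResult(False, o_ij, p_value, None, (), None)
    if p_value >= params.p_cutoff:
        return no_merge
    positive = [ov for _, _, ov in pairs if ov > 0]
    if not positive:
        return no_merge
    values, counts = np.unique(positive, return_counts=True)
    l_o = int(values[counts == counts.max()].max())  # modal; ties -> larger
    l_x = _width_of(c_i) + _width_of(c_j) - l_o
    merged = []
    for vi, vj, ov in pairs:
        if ov != l_o:
            continue
        row_i, start_i, w_i = vi
        seq, s_i, e_i = matrix.to_forward_span(row_i, start_i, w_i)
        row_j, start_j, w_j = vj
        _, s_j, e_j = matrix.to_forward_span(row_j, start_j, w_j)
        fwd_start, fwd_end = min(s_i, s_j), max(e_i, e_j)
        n_row = matrix.row_length(row_i)
        if matrix.is_reverse_row(row_i):
            start = n_row - fwd_end
        else:
            start = fwd_start
        merged.append((row_i, start, l_x))
    return MergeResult(True, o_ij, p_value, l_o, tuple(sorted(merged)), l_x)


def _merge_round(
    seeds: list[MotifSeed], matrix: StrandCoverageMatrix, params: BookendParams
) -> tuple[list[MotifSeed], bool]:
    """One greedy most-significant-first pass; each seed merges at most once."""
    results = []
    for i in range(len(seeds)):
        for j in range(i + 1, len(seeds)):
            res = merge_pair(seeds[i], seeds[j], matrix, params)
            log.debug(
                "bookend %d~%d: o=%d n_i=%d n_j=%d P=%.3g %s",
                i, j, res.o_ij, seeds[i].size, seeds[j].size, res.p_value,
                f"merge l_o={res.l_o}" if res.merged else "keep",
            )
            # a merge must leave at least a minimal clique's worth of
            # support; pairs whose modal-overlap set is thinner would
            # replace well-supported motifs with near-empty ones
            if res.merged and len(res.instances) >= 3:
                results.append((res.p_value, i, j, res))
    results.sort(key=lambda r: (r[0], r[1], r[2]))
    consumed: set[int] = set()
    merged_seeds: list[MotifSeed] = []
    for _, i, j, res in results:
        if i in consumed or j in consumed:
            continue
        consumed.update((i, j))
        merged_seeds.append(
            MotifSeed(
                instances=res.instances,
                width=res.l_x,
                l_o=res.l_o,
                source_l=seeds[i].source_l,
            )
        )
    survivors = [s for i, s in enumerate(seeds) if i not in consumed]
    return merged_seeds + survivors, bool(merged_seeds)


def bookend_all(
    motifs: list[PotentialMotif],
    matrix: StrandCoverageMatrix,
    params: BookendParams,
) -> list[MotifSeed]:
    """Iterated greedy pairwise merging over all potential motifs.

    Within a round, every unordered pair is tested and merges apply in
    ascending p-value order with each motif participating at most once.
    By default a single round is run; additional rounds (max_rounds > 1)
    re-test the merged seeds, which lets wider motifs assemble stepwise
    but erodes instance support, since every merge keeps only the pairs
    at the modal overlap. Strand or shift twins of one motif (modal
    overlap equal to the width) simply pool their instances without
    widening.
    """
    seeds = [
        MotifSeed(
            instances=tuple((r, s, m.l) for r, s in m.instances),
            width=m.l,
            l_o=m.l,
            source_l=m.l,
        )
        for m in motifs
    ]
    for round_no in range(params.max_rounds):
        seeds, changed = _merge_round(seeds, matrix, params)
        if not changed:
            break
        log.debug("bookend round %d: %d seeds remain", round_no + 1, len(seeds))
    return seeds
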