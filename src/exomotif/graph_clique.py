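"""Alignment graph construction and disjoint maximal clique detection.

Segments whose combined weight f' = f * (M2_ij + M2_pq) ranks in the top
beta within their row pair become graph vertices joined by an edge, so the
graph concentrates on positions with consistent cross-sequence support.
Potential motifs are then disjoint maximal cliques extracted by a greedy
heuristic: seed at the highest-degree unused vertex, grow by the candidate
adjacent to every current member with the largest summed edge weight into
the clique, subject to at most one instance per original peak (either
strand), and remove used vertices between cliques.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .alignment import AlignmentParams, PairScorer, _rank_mask, first_pass, second_pass, eligible_row_pairs
from .weighting import StrandCoverageMatrix, WeightedPeakSet, build_strand_matrix

log = logging.getLogger(__name__)

Vertex = tuple[int, int]  # (strand row, start)


@dataclass
class GraphParams:
    """beta: graph rank cutoff; min_clique_size: smallest clique kept;
    max_motifs: cap on finally reported motifs (every qualifying clique
    still feeds the width-merging stage)."""

    beta: int = 3
    min_clique_size: int = 3
    max_motifs: int = 10

    def __post_init__(self) -> None:
        if self.beta < 1:
            raise ValueError("beta must be >= 1")
        if self.min_clique_size < 2:
            raise ValueError("min_clique_size must be >= 2")


class AlignmentGraph:
    """Undirected weighted graph over l-segment vertices.

    Vertices are (row, start) pairs; edges only link rows of distinct
    original peaks and keep the maximum weight seen for a duplicate pair.
    """

    def __init__(self, l: int):
        self.l = l
        self.adj: dict[Vertex, dict[Vertex, float]] = {}

    def add_edge(self, u: Vertex, v: Vertex, weight: float) -> None:
        if u == v:
            raise ValueError("self-loops are not allowed")
        if u[0] // 2 == v[0] // 2:
            raise ValueError("edge endpoints must lie on distinct peaks")
        self.adj.setdefault(u, {})
        self.adj.setdefault(v, {})
        w = max(weight, self.adj[u].get(v, -np.inf))
        self.adj[u][v] = w
        self.adj[v][u] = w

    @property
    def vertices(self) -> list[Vertex]:
        return list(self.adj)

    def n_edges(self) -> int:
        return sum(len(nbrs) for nbrs in self.adj.values()) // 2

    def degree(self, v: Vertex) -> int:
        return len(self.adj.get(v, {}))

    def weight_sum(self, v: Vertex) -> float:
        return sum(self.adj.get(v, {}).values())

    def edge_list(self):
        seen = set()
        for u, nbrs in self.adj.items():
            for v, w in nbrs.items():
                if (v, u) not in seen:
                    seen.add((u, v))
                    yield u, v, w

    def dump_edges(self, path) -> None:
        """Debug TSV: row_i, pos_i, row_p, pos_q, weight."""
        with open(path, "w") as fh:
            for (r1, p1), (r2, p2), w in sorted(self.edge_list()):
                fh.write(f"{r1}\t{p1}\t{r2}\t{p2}\t{w:.6g}\n")


@dataclass
class PotentialMotif:
    """A clique of mutually supporting segments: one candidate motif."""

    instances: tuple[Vertex, ...]
    l: int
    score: float  # mean edge weight within the clique

    @property
    def size(self) -> int:
        return len(self.instances)


def build_graph(
    matrix: StrandCoverageMatrix,
    m2: list[np.ndarray],
    params: AlignmentParams,
    graph_params: GraphParams,
    scorer: PairScorer | None = None,
) -> AlignmentGraph:
    """Connect segment pairs ranking in the top beta of f' per row pair."""
    scorer = scorer or PairScorer(matrix, params.l)
    graph = AlignmentGraph(params.l)
    for r1, r2 in eligible_row_pairs(matrix.n_rows):
        f = scorer.f_matrix(r1, r2)
        fprime = f * (m2[r1][:, None] + m2[r2][None, :])
        mask = _rank_mask(fprime, graph_params.beta)
        for j, q in zip(*np.nonzero(mask)):
            graph.add_edge((r1, int(j)), (r2, int(q)), float(fprime[j, q]))
    log.debug("graph: %d vertices, %d edges", len(graph.adj), graph.n_edges())
    return graph


def _seed_order_key(graph: AlignmentGraph, v: Vertex):
    return (-graph.degree(v), -graph.weight_sum(v), v)


def find_disjoint_cliques(graph: AlignmentGraph, params: GraphParams) -> list[PotentialMotif]:
    """Greedy disjoint maximal cliques, at most one instance per peak.

    Seeds are taken in order of degree (ties: incident weight sum, then
    lexicographic (row, pos)); growth repeatedly adds the unused vertex
    adjacent to all members with maximal summed edge weight into the
    clique, rejecting vertices on an already-represented peak (either
    strand row). Cliques below min_clique_size are discarded but their
    seed is retired, and accepted cliques consume their vertices, making
    the output disjoint. Results are sorted by (size desc, score desc);
    every qualifying clique is returned.
    """
    used: set[Vertex] = set()
    retired: set[Vertex] = set()
    motifs: list[PotentialMotif] = []
    while True:
        candidates = [v for v in graph.adj if v not in used and v not in retired]
        if not candidates:
            break
        seed = min(candidates, key=lambda v: _seed_order_key(graph, v))
        clique = [seed]
        seqs = {seed[0] // 2}
        frontier = {
            v: w for v, w in graph.adj[seed].items() if v not in used and v[0] // 2 not in seqs
        }
        while frontier:
            # candidate adjacent to all members with max summed weight in
            best = min(frontier.items(), key=lambda item: (-item[1], item[0]))[0]
            clique.append(best)
            seqs.add(best[0] // 2)
            new_frontier = {}
            for v, w in frontier.items():
                if v == best or v[0] // 2 in seqs:
                    continue
                wb = graph.adj[best].get(v)
                if wb is not None:
                    new_frontier[v] = w + wb
            frontier = new_frontier
        if len(clique) < params.min_clique_size:
            # retire the seed from seeding but keep it available for
            # growth into later cliques
            retired.add(seed)
            continue
        used.update(clique)
        weights = [
            graph.adj[u][v] for i, u in enumerate(clique) for v in clique[i + 1 :]
        ]
        motifs.append(
            PotentialMotif(
                instances=tuple(sorted(clique)),
                l=graph.l,
                score=float(np.mean(weights)),
            )
        )
    motifs.sort(key=lambda m: (-m.size, -m.score, m.instances))
    return motifs


def discover_potential_motifs(
    peaks: WeightedPeakSet,
    align_params: AlignmentParams,
    graph_params: GraphParams,
) -> list[PotentialMotif]:
    """Run stages 1-3 for every l in the configured range and pool results.

    Each potential motif is tagged with the l it was discovered at.
    """
    out: list[PotentialMotif] = []
    matrix = build_strand_matrix(peaks)
    for l in align_params.l_values():
        params_l = AlignmentParams(
            l=l, f_threshold=align_params.f_threshold, alpha=align_params.alpha
        )
        scorer = PairScorer(matrix, l)
        m1 = first_pass(matrix, params_l, scorer)
        m2, _ = second_pass(matrix, m1, params_l, scorer)
        graph = build_graph(matrix, m2, params_l, graph_params, scorer)
        out.extend(find_disjoint_cliques(graph, graph_params))
    return out
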