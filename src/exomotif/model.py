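"""Model/Results surface tying the discovery stages together.

``MotifDiscovery`` is constructed from a peak set (with or without
coverage) plus the tuning parameters, and ``fit()`` runs the full
pipeline — strand expansion, two-stage alignment, graph construction,
disjoint clique detection, bookend width merging and PWM expansion —
returning a ``MotifDiscoveryResults`` that carries the discovered motif
models, per-stage diagnostics and a ``summary()`` table, and knows how
to write MEME/BED artifacts and to evaluate itself by pAUC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import io_formats
from .alignment import AlignmentParams
from .bookend import BookendParams, bookend_all
from .evaluation import evaluate_motif, sample_negatives
from .graph_clique import GraphParams, discover_potential_motifs
from .refinement import (
    MotifModel,
    estimate_background,
    expand_instances,
    match_score,
    model_from_seed,
    write_instances_bed,
)
from .weighting import StrandCoverageMatrix, WeightedPeakSet, build_strand_matrix

log = logging.getLogger(__name__)


class MotifDiscovery:
    """Coverage-weighted de novo motif discovery model.

    Parameters
    ----------
    peaks : WeightedPeakSet or sequence of PeakRecord
        The positive (peak) sequences; raw coverage is normalised on
        construction. ``mode='basic'`` ignores coverage entirely.
    l : int
        Seed segment width for the alignment stages (default 14).
    f_threshold, alpha : float, int
        Stage increment rules: binomial significance threshold and
        per-row-pair rank cutoff.
    beta : int
        Rank cutoff for graph edges.
    d, p_cutoff : int, float
        Bookend co-occurrence window and significance level.
    t : int
        Flank width of the coverage windows in the match score.
    background : array or sequences, optional
        Genome sequences (or 4 probabilities) for the background model;
        defaults to the peak sequences themselves.
    """

    def __init__(
        self,
        peaks,
        mode: str = "cov",
        l: int = 14,
        l_range: tuple[int, int] | None = None,
        f_threshold: float = 3.0,
        alpha: int = 5,
        beta: int = 3,
        min_clique_size: int = 3,
        max_motifs: int = 10,
        d: int = 25,
        p_cutoff: float = 0.05,
        t: int = 2,
        expand_iterations: int = 1,
        bookend_rounds: int = 1,
        background=None,
    ):
        if mode not in ("cov", "basic"):
            raise ValueError("mode must be 'cov' or 'basic'")
        if not isinstance(peaks, WeightedPeakSet):
            peaks = WeightedPeakSet.from_records(peaks, mode=mode)
        elif mode == "basic":
            peaks = WeightedPeakSet.from_records(peaks.records, mode="basic")
        self.peaks = peaks
        self.mode = mode
        self.align_params = AlignmentParams(
            l=l, f_threshold=f_threshold, alpha=alpha, l_range=l_range
        )
        self.graph_params = GraphParams(
            beta=beta, min_clique_size=min_clique_size, max_motifs=max_motifs
        )
        self.bookend_params = BookendParams(
            d=d, p_cutoff=p_cutoff, max_rounds=bookend_rounds
        )
        self.t = t
        self.expand_iterations = expand_iterations
        if background is None:
            self.background = estimate_background([r.sequence for r in peaks.records])
            log.info("background estimated from the peak sequences")
        elif isinstance(background, (list, tuple, np.ndarray)) and np.ndim(background) == 1 and len(background) == 4 and not isinstance(background[0], str):
            self.background = np.asarray(background, dtype=float)
            self.background = self.background / self.background.sum()
        else:
            self.background = estimate_background(background)

    # -- constructors -------------------------------------------------

    @classmethod
    def from_fasta(cls, path, **kwargs) -> "MotifDiscovery":
        """Plain FASTA input: runs in basic (sequence-only) mode."""
        kwargs.setdefault("mode", "basic")
        return cls(io_formats.read_fasta(path), **kwargs)

    @classmethod
    def from_coverage_fasta(cls, path, **kwargs) -> "MotifDiscovery":
        return cls(io_formats.read_coverage_fasta(path), **kwargs)

    @classmethod
    def from_genome_bed(cls, genome, bed, coverage=None, **kwargs) -> "MotifDiscovery":
        """Extract peaks from a genome + BED, optionally with coverage tracks."""
        if not isinstance(genome, io_formats.GenomeIndex):
            genome = io_formats.GenomeIndex.from_fasta(genome)
        intervals = [(c, s, e) for c, s, e, _, _ in io_formats.read_bed(bed)]
        records = io_formats.extract_peaks(genome, bed)
        if coverage is not None:
            tracks = coverage if isinstance(coverage, (list, tuple)) else [coverage]
            tracks = [
                io_formats.open_coverage_track(tr) if isinstance(tr, (str,)) or hasattr(tr, "__fspath__") else tr
                for tr in tracks
            ]
            records = io_formats.attach_coverage(records, tracks, intervals)
        else:
            kwargs.setdefault("mode", "basic")
        kwargs.setdefault("background", [genome.fetch(c, 0, n) for c, n in genome.contigs.items()])
        return cls(records, **kwargs)

    # -- fitting ------------------------------------------------------

    def fit(self) -> "MotifDiscoveryResults":
        matrix = build_strand_matrix(self.peaks)
        mh_norm = matrix.row_normalized()
        potentials = discover_potential_motifs(
            self.peaks, self.align_params, self.graph_params
        )
        log.info("clique stage: %d potential motifs", len(potentials))
        seeds = bookend_all(potentials, matrix, self.bookend_params) if potentials else []
        models: list[MotifModel] = []
        for seed in seeds:
            if seed.size < 2:
                continue
            model = model_from_seed(seed, matrix, self.background, t=self.t)
            model = expand_instances(model, matrix, mh_norm, self.expand_iterations)
            models.append(model)
        scored = []
        for model in models:
            total = sum(
                match_score((row, start), model, matrix, mh_norm)
                for row, start, _ in model.instances
            )
            scored.append((model, total))
        # rank by total match score: instance-count alone would favour
        # washed-out models whose permissive PWMs over-expand
        scored.sort(key=lambda ms: (-ms[1], -ms[0].nsites))
        scored = scored[: self.graph_params.max_motifs]
        ranked = []
        for rank, (model, total) in enumerate(scored, start=1):
            model.name = f"motif_{rank}"
            ranked.append((model, total))
        return MotifDiscoveryResults(
            model=self,
            matrix=matrix,
            mh_norm=mh_norm,
            potentials=potentials,
            seeds=seeds,
            motifs=[m for m, _ in ranked],
            total_scores=[s for _, s in ranked],
        )


@dataclass
class MotifDiscoveryResults:
    """Fitted motifs plus the intermediate evidence behind them."""

    model: MotifDiscovery
    matrix: StrandCoverageMatrix
    mh_norm: list[np.ndarray]
    potentials: list
    seeds: list
    motifs: list[MotifModel]
    total_scores: list[float]

    @property
    def top_motif(self) -> MotifModel | None:
        return self.motifs[0] if self.motifs else None

    def summary(self) -> str:
        """Human-readable table of the discovered motifs."""
        header = (
            f"Motif discovery ({self.model.mode} mode): "
            f"{self.model.peaks.m} peaks, l={self.model.align_params.l}, "
            f"{len(self.potentials)} potential motifs, {len(self.motifs)} final"
        )
        if not self.motifs:
            return header + "\n(no motifs found)"
        frame = self.to_frame()
        return header + "\n" + frame.to_string(index=False)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for model, total in zip(self.motifs, self.total_scores):
            rows.append(
                {
                    "motif": model.name,
                    "width": model.width,
                    "nsites": model.nsites,
                    "consensus": model.consensus,
                    "info_bits": round(self.information_content(model), 2),
                    "total_score": round(total, 2),
                }
            )
        return pd.DataFrame(rows)

    @staticmethod
    def information_content(model: MotifModel) -> float:
        """Total information (bits) of the motif's frequency columns."""
        freq = model.frequencies
        return float((freq * np.log2(freq / model.background[:, None])).sum())

    def write_meme(self, path) -> None:
        io_formats.write_meme_pwm(self.motifs, path, background=self.model.background)

    def write_bed(self, path) -> None:
        write_instances_bed(self.motifs, self.matrix, path)

    def evaluate(self, negatives=None, genome=None, seed: int = 0, all_motifs: bool = False) -> pd.DataFrame:
        """pAUC metrics against negatives (given, or sampled from a genome)."""
        if not self.motifs:
            raise ValueError("no motifs to evaluate")
        if negatives is None:
            if genome is None:
                raise ValueError("provide negatives or a genome to sample them from")
            negatives = sample_negatives(genome, self.model.peaks.lengths, seed)
        targets = self.motifs if all_motifs else [self.motifs[0]]
        rows = []
        for model in targets:
            roc = evaluate_motif(model, self.model.peaks.records, negatives)
            rows.append(
                {
                    "motif": model.name,
                    "pauc_sensitivity": roc.pauc_sensitivity,
                    "pauc_specificity": roc.pauc_specificity,
                }
            )
        return pd.DataFrame(rows)
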