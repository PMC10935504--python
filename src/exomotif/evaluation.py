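"""Sequence bi-classification assessment with restricted-interval pAUC.

Discovered motifs are judged by how well their best PWM hit separates
bound (peak) sequences from genome-sampled negatives. The ROC curve is
summarised over its critical corners only: pAUC(specificity) integrates
TPR over FPR in (0, 0.2) and pAUC(sensitivity) integrates (1 - FPR)
over TPR in (0.8, 1.0). Both raw areas are standardised (McClish) so a
perfect classifier scores 1.0 and an uninformative one 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import GenomeIndex, PeakRecord
from .refinement import MotifModel
from .weighting import encode, reverse_complement


@dataclass
class ROCResult:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    pauc_sensitivity: float
    pauc_specificity: float


def score_sequence(seq: str, model: MotifModel) -> float:
    """Best plain log-odds window score over both strands.

    The coverage factor is deliberately excluded: negative sequences
    carry no coverage, so classification uses the PWM alone.
    """
    if len(seq) < model.width:
        raise ValueError(f"sequence shorter than motif width {model.width}")
    sm = model.scoring_matrix()
    cols = np.arange(model.width)
    best = -np.inf
    for s in (seq, reverse_complement(seq)):
        windows = np.lib.stride_tricks.sliding_window_view(encode(s), model.width)
        best = max(best, float(sm[windows, cols[None, :]].sum(axis=1).max()))
    return best


def _roc_points(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """ROC by descending-threshold sweep; tied scores collapse to one point."""
    scores = np.concatenate([pos, neg])
    labels = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
    order = np.argsort(-scores, kind="mergesort")
    scores, labels = scores[order], labels[order]
    distinct = np.nonzero(np.diff(scores))[0]
    idx = np.r_[distinct, len(scores) - 1]
    tps = np.cumsum(labels)[idx]
    fps = np.cumsum(1 - labels)[idx]
    tpr = np.r_[0.0, tps / len(pos)]
    fpr = np.r_[0.0, fps / len(neg)]
    thresholds = np.r_[np.inf, scores[idx]]
    return thresholds, fpr, tpr


def _band_area(x: np.ndarray, y: np.ndarray, lo: float, hi: float) -> float:
    """Trapezoidal area of the corner-sequence curve y(x) over [lo, hi].

    Each corner-to-corner segment is clipped to the band and its
    trapezoid added; vertical runs (repeated x, e.g. tied scores) have
    zero width along x and contribute nothing. x must be nondecreasing.
    """
    x0, x1 = x[:-1], x[1:]
    y0, y1 = y[:-1], y[1:]
    a = np.maximum(x0, lo)
    b = np.minimum(x1, hi)
    run = np.where(x1 > x0, x1 - x0, 1.0)
    ya = y0 + (y1 - y0) * (a - x0) / run
    yb = y0 + (y1 - y0) * (b - x0) / run
    seg = 0.5 * (ya + yb) * (b - a)
    return float(seg[(b > a) & (x1 > x0)].sum())


def _standardize(area: float, lo: float, hi: float, random_area: float) -> float:
    """McClish transform: random -> 0.5, perfect -> 1.0."""
    perfect = hi - lo
    return 0.5 * (1.0 + (area - random_area) / (perfect - random_area))


def partial_auc(pos_scores, neg_scores) -> ROCResult:
    """Restricted-interval pAUCs of a two-class score separation.

    pauc_specificity summarises TPR over the FPR band (0, 0.2);
    pauc_sensitivity summarises specificity (1 - FPR) over the TPR band
    (0.8, 1.0), the horizontal analogue. Both are standardised to [0, 1]
    with 0.5 for an uninformative classifier, making the metrics
    invariant to monotone transforms of the scores.
    """
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score vectors must be nonempty")
    thresholds, fpr, tpr = _roc_points(pos, neg)

    area_spec = _band_area(fpr, tpr, 0.0, 0.2)
    # random: integral of x over (0, 0.2) = 0.02
    pauc_specificity = _standardize(area_spec, 0.0, 0.2, 0.02)

    # integrate FPR along the TPR axis; curve must be nondecreasing in TPR
    area_fpr = _band_area(tpr, fpr, 0.8, 1.0)
    area_sens = (1.0 - 0.8) - area_fpr  # area of (1 - FPR) over the band
    # random: integral of (1 - t) over (0.8, 1) = 0.02
    pauc_sensitivity = _standardize(area_sens, 0.8, 1.0, 0.02)

    return ROCResult(
        thresholds=thresholds,
        fpr=fpr,
        tpr=tpr,
        pauc_sensitivity=float(np.clip(pauc_sensitivity, 0.0, 1.0)),
        pauc_specificity=float(np.clip(pauc_specificity, 0.0, 1.0)),
    )


def evaluate_motif(model: MotifModel, positives, negatives) -> ROCResult:
    """pAUC metrics of one motif against positive/negative sequence sets."""
    pos = [score_sequence(getattr(r, "sequence", r), model) for r in positives]
    neg = [score_sequence(getattr(r, "sequence", r), model) for r in negatives]
    return partial_auc(pos, neg)


def sample_negatives(
    genome: GenomeIndex, lengths, seed: int | np.random.Generator = 0
) -> list[PeakRecord]:
    """Uniformly placed genome intervals matching the requested lengths.

    Intervals with more than 50% N are rejected and resampled (up to 100
    tries each). Deterministic under the seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    contigs = [(name, size) for name, size in genome.contigs.items()]
    records = []
    for idx, length in enumerate(lengths):
        eligible = [(name, size) for name, size in contigs if size >= length]
        if not eligible:
            raise ValueError(f"no contig long enough for length {length}")
        for _ in range(100):
            name, size = eligible[rng.integers(len(eligible))]
            start = int(rng.integers(size - length + 1))
            seq = genome.fetch(name, start, start + length)
            if seq.count("N") <= 0.5 * length:
                records.append(
                    PeakRecord(id=f"neg{idx}_{name}:{start}-{start + length}", sequence=seq)
                )
                break
        else:
            raise RuntimeError(f"could not place a negative of length {length}")
    return records
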