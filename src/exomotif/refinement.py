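"""PWM construction, coverage-weighted match scoring and instance expansion.

A motif's PWM is the log2-odds of position-specific nucleotide
frequencies (Laplace pseudocount 1, split 0.25 per base) against the
genomic background q. The match score of a candidate segment combines
the PWM log-odds sum with the local coverage support,

    S = 1/2 (max_{j'-t<=j''<=j'} w_j'' + max_{j'<=j''<=j'+l_o+t} w_j'') * sum PWM,

where w is the row-max-normalised coverage and t a small flank (default
2). Expansion admits every segment scoring strictly above the weakest
current instance, then rebuilds the PWM from the enlarged set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .bookend import MotifSeed
from .weighting import StrandCoverageMatrix, encode

log = logging.getLogger(__name__)

_BASES = "ACGT"


def estimate_background(sequences) -> np.ndarray:
    """Mononucleotide background frequencies (A, C, G, T); N excluded.

    Pass genome contig sequences when available, otherwise the peaks
    themselves. Zero frequencies are lifted to 1e-6 and renormalised so
    log-odds stay finite.
    """
    counts = np.zeros(4)
    for seq in sequences:
        code = encode(seq)
        counts += np.bincount(code[code < 4], minlength=4)
    total = counts.sum()
    if total == 0:
        raise ValueError("no usable (non-N) bases to estimate background from")
    q = counts / total
    q = np.maximum(q, 1e-6)
    return q / q.sum()


@dataclass
class MotifModel:
    """A discovered motif: instances, counts, PWM and provenance.

    ``instances`` are (row, start, width) segments on strand rows of the
    originating peak set. ``pwm`` holds log2(p(i,j)/q(i)); ``frequencies``
    the pseudocounted column probabilities. ``l_o`` records the overlap
    width the bookend stage used (the full width for unmerged seeds) and
    bounds the second coverage window of the match score.
    """

    instances: tuple[tuple[int, int, int], ...]
    width: int
    counts: np.ndarray
    frequencies: np.ndarray
    pwm: np.ndarray
    background: np.ndarray
    l_o: int
    t: int = 2
    name: str = "motif"

    @property
    def nsites(self) -> int:
        return len(self.instances)

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.frequencies.argmax(axis=0))

    def scoring_matrix(self) -> np.ndarray:
        """5 x width PWM with an extra N row holding each column's mean."""
        return np.vstack([self.pwm, self.pwm.mean(axis=0)])


def instance_sequence(matrix: StrandCoverageMatrix, inst: tuple[int, int, int]) -> str:
    row, start, width = inst
    return matrix.sequences[row][start : start + width]


def _count_matrix(seqs: list[str], width: int) -> np.ndarray:
    counts = np.zeros((4, width))
    for seq in seqs:
        if len(seq) != width:
            raise ValueError(f"instance length {len(seq)} != motif width {width}")
        code = encode(seq)
        for j, c in enumerate(code):
            if c < 4:
                counts[c, j] += 1
            else:  # N spreads evenly
                counts[:, j] += 0.25
    return counts


def build_pwm(
    instances,
    matrix: StrandCoverageMatrix,
    background: np.ndarray,
    l_o: int | None = None,
    t: int = 2,
    name: str = "motif",
) -> MotifModel:
    """Build a MotifModel from aligned equal-width instances.

    Column frequencies use a Laplace pseudocount of 1 distributed 0.25
    per base: p(i,j) = (count + 0.25) / (n + 1).
    """
    instances = tuple(sorted(instances))
    if len(instances) < 2:
        raise ValueError("need at least 2 instances to build a PWM")
    width = instances[0][2]
    seqs = [instance_sequence(matrix, inst) for inst in instances]
    counts = _count_matrix(seqs, width)
    n = len(seqs)
    freq = (counts + 0.25) / (n + 1)
    pwm = np.log2(freq / background[:, None])
    return MotifModel(
        instances=instances,
        width=width,
        counts=counts,
        frequencies=freq,
        pwm=pwm,
        background=np.asarray(background, dtype=float),
        l_o=width if l_o is None else l_o,
        t=t,
        name=name,
    )


def model_from_seed(
    seed: MotifSeed,
    matrix: StrandCoverageMatrix,
    background: np.ndarray,
    t: int = 2,
    name: str = "motif",
) -> MotifModel:
    return build_pwm(seed.instances, matrix, background, l_o=seed.l_o, t=t, name=name)


def _pwm_window_sums(model: MotifModel, code: np.ndarray) -> np.ndarray:
    """Log-odds sum of every width-window of an encoded row sequence."""
    w = model.width
    if len(code) < w:
        return np.zeros(0)
    windows = np.lib.stride_tricks.sliding_window_view(code, w)
    sm = model.scoring_matrix()
    return sm[windows, np.arange(w)[None, :]].sum(axis=1)


def _coverage_factor(model: MotifModel, mh_row: np.ndarray, start: int) -> float:
    t, l_o = model.t, model.l_o
    n = len(mh_row)
    left = mh_row[max(0, start - t) : start + 1]
    right = mh_row[start : min(n, start + l_o + t + 1)]
    return 0.5 * (left.max(initial=0.0) + right.max(initial=0.0))


def match_score(
    segment: tuple[int, int],
    model: MotifModel,
    matrix: StrandCoverageMatrix,
    mh_norm: list[np.ndarray],
) -> float:
    """Coverage-weighted PWM match score of one width-l_x segment.

    In basic mode (all coverage 1) the coverage factor is 1 and S
    reduces to the plain log-odds sum. N bases contribute the PWM
    column mean.
    """
    row, start = segment
    code = matrix.codes[row]
    if start < 0 or start + model.width > len(code):
        raise ValueError(f"segment ({row}, {start}) out of bounds")
    sm = model.scoring_matrix()
    logodds = float(sm[code[start : start + model.width], np.arange(model.width)].sum())
    return _coverage_factor(model, mh_norm[row], start) * logodds


def _overlaps(a_start: int, b_start: int, width: int) -> int:
    return max(0, min(a_start, b_start) + width - max(a_start, b_start))


def expand_instances(
    model: MotifModel,
    matrix: StrandCoverageMatrix,
    mh_norm: list[np.ndarray],
    iterations: int = 1,
) -> MotifModel:
    """Admit all segments outscoring the weakest current instance.

    The threshold is the minimum match score over current instances;
    every width-l_x segment on any strand row with a strictly greater
    score is added, except candidates overlapping an already kept
    instance on the same row by more than half the width (candidates are
    ranked by score so the strongest of a shifted stack survives).
    Existing instances are never removed; the PWM is rebuilt from the
    expanded set. Repeats for ``iterations`` rounds or until fixed point.
    """
    for _ in range(iterations):
        inst_scores = [
            match_score((row, start), model, matrix, mh_norm)
            for row, start, _ in model.instances
        ]
        threshold = min(inst_scores)
        candidates = []
        for row in range(matrix.n_rows):
            sums = _pwm_window_sums(model, matrix.codes[row])
            for start in range(sums.size):
                s = _coverage_factor(model, mh_norm[row], start) * float(sums[start])
                if s > threshold:
                    candidates.append((s, row, int(start)))
        candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
        kept = {(row, start) for row, start, _ in model.instances}
        added = []
        for s, row, start in candidates:
            if (row, start) in kept:
                continue
            clash = any(
                r == row and _overlaps(p, start, model.width) > model.width / 2
                for r, p in kept
            )
            if clash:
                continue
            kept.add((row, start))
            added.append((row, start, model.width))
        if not added:
            break
        model = build_pwm(
            tuple(model.instances) + tuple(added),
            matrix,
            model.background,
            l_o=model.l_o,
            t=model.t,
            name=model.name,
        )
    return model


def write_instances_bed(models, matrix: StrandCoverageMatrix, path) -> None:
    """BED6 of motif instances in peak-relative forward coordinates."""
    with open(path, "w") as fh:
        for model in models:
            for row, start, width in model.instances:
                seq_idx, s, e = matrix.to_forward_span(row, start, width)
                rec = matrix.peaks.records[seq_idx]
                strand = "-" if matrix.is_reverse_row(row) else "+"
                fh.write(f"{rec.id}\t{s}\t{e}\t{model.name}\t0\t{strand}\n")
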