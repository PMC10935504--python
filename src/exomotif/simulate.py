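"""Synthetic peak sets with planted motifs and known ground truth.

The generator emulates what the pipeline consumes: m peak sequences with
background bases i.i.d. from q, a motif instance sampled column-wise from
a known PWM planted on a uniform position and strand in a chosen fraction
of peaks, and a per-base coverage track that is flat (baseline 1) except
for a triangular bump centred on each planted site — the coverage
footprint a bound TF leaves in ChIP-exo data, simplified to an exact,
integer-friendly shape. Everything is deterministic under the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import PeakRecord, write_coverage_fasta
from .weighting import WeightedPeakSet, reverse_complement

_BASES = "ACGT"


@dataclass
class PlantedSite:
    seq_index: int
    position: int  # forward-strand start of the embedded instance
    strand: str  # "+"/"-": orientation of the planted motif
    width: int


@dataclass
class PlantSpec:
    """Study conditions for one synthetic dataset.

    coverage_shape is (bump height, half-width in bp) of the triangular
    coverage bump added on top of a baseline of 1 at each planted site.
    """

    pwm: np.ndarray  # 4 x w column frequencies (A,C,G,T)
    plant_rate: float = 0.9
    m: int = 20
    peak_len: int = 200
    coverage_shape: tuple[float, float] = (9.0, 20.0)
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    seed: int = 0

    def __post_init__(self) -> None:
        self.pwm = np.asarray(self.pwm, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.pwm.shape[0] != 4:
            raise ValueError("pwm must be 4 x width")
        if not np.allclose(self.pwm.sum(axis=0), 1.0):
            raise ValueError("pwm columns must each sum to 1")
        if not 0.0 <= self.plant_rate <= 1.0:
            raise ValueError("plant_rate must lie in [0, 1]")

    @property
    def width(self) -> int:
        return self.pwm.shape[1]


def pwm_from_consensus(consensus: str, dominant: float = 0.97) -> np.ndarray:
    """One dominant base per column, the rest sharing the remainder.

    dominant=0.97 gives ~1.8 bits of information per column.
    """
    pwm = np.full((4, len(consensus)), (1.0 - dominant) / 3.0)
    for j, base in enumerate(consensus.upper()):
        pwm[_BASES.index(base), j] = dominant
    return pwm


def _sample_instance(pwm: np.ndarray, rng: np.random.Generator) -> str:
    return "".join(
        _BASES[rng.choice(4, p=pwm[:, j] / pwm[:, j].sum())] for j in range(pwm.shape[1])
    )


def generate_planted_dataset(spec: PlantSpec) -> tuple[WeightedPeakSet, list[PlantedSite]]:
    """Peaks with planted PWM instances and coverage bumps at the sites.

    Exactly round(plant_rate * m) peaks (chosen at random) carry one
    instance each, on a uniform strand and position; the rest are pure
    background. Coverage is baseline 1 plus the triangular bump, then
    log-ratio normalised.
    """
    w = spec.width
    if w > spec.peak_len:
        raise ValueError(f"motif width {w} exceeds peak length {spec.peak_len}")
    rng = np.random.default_rng(spec.seed)
    n_planted = int(round(spec.plant_rate * spec.m))
    planted_idx = set(rng.choice(spec.m, size=n_planted, replace=False).tolist())
    height, half_width = spec.coverage_shape
    q = spec.background / spec.background.sum()

    records, truth = [], []
    for i in range(spec.m):
        seq = list(rng.choice(list(_BASES), size=spec.peak_len, p=q))
        cov = np.ones(spec.peak_len)
        if i in planted_idx:
            pos = int(rng.integers(spec.peak_len - w + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            inst = _sample_instance(spec.pwm, rng)
            if strand == "-":
                inst = reverse_complement(inst)
            seq[pos : pos + w] = list(inst)
            center = pos + w / 2.0
            offsets = np.arange(spec.peak_len) + 0.5
            cov += height * np.maximum(0.0, 1.0 - np.abs(offsets - center) / half_width)
            truth.append(PlantedSite(i, pos, strand, w))
        records.append(PeakRecord(id=f"peak{i}", sequence="".join(seq), coverage=cov))
    return WeightedPeakSet.from_records(records), truth


def generate_split_motif_dataset(
    spec: PlantSpec, total_width: int
) -> tuple[WeightedPeakSet, list[PlantedSite]]:
    """Plant one contiguous motif wide enough that two l-mers must tile it.

    Used to exercise bookend width merging: e.g. total_width 22 with
    discovery at l = 14 leaves a modal overlap of 6 between the two
    covering 14-mers. spec.pwm must have total_width columns.
    """
    if spec.width != total_width:
        raise ValueError(f"spec.pwm has width {spec.width}, expected {total_width}")
    return generate_planted_dataset(spec)


def export_dataset(peaks: WeightedPeakSet, truth, covfa_path, bed_path) -> None:
    """Emit the generated set as coverage-FASTA plus a BED truth file."""
    write_coverage_fasta(peaks.records, covfa_path)
    with open(bed_path, "w") as fh:
        for site in truth:
            rec = peaks.records[site.seq_index]
            fh.write(
                f"{rec.id}\t{site.position}\t{site.position + site.width}\t"
                f"planted\t0\t{site.strand}\n"
            )


def site_recovery(truth, models, matrix, min_overlap_frac: float = 0.5) -> float:
    """Fraction of planted sites overlapped enough by reported instances.

    A site counts as recovered when some instance (of any given model)
    on the same peak overlaps at least ``min_overlap_frac`` of the
    planted width. Returns 1.0 trivially for empty truth.
    """
    if not truth:
        return 1.0
    if not isinstance(models, (list, tuple)):
        models = [models]
    spans_by_seq: dict[int, list[tuple[int, int]]] = {}
    for model in models:
        for row, start, width in model.instances:
            seq_idx, s, e = matrix.to_forward_span(row, start, width)
            spans_by_seq.setdefault(seq_idx, []).append((s, e))
    hits = 0
    for site in truth:
        lo, hi = site.position, site.position + site.width
        need = min_overlap_frac * site.width
        for s, e in spans_by_seq.get(site.seq_index, []):
            if min(hi, e) - max(lo, s) >= need:
                hits += 1
                break
    return hits / len(truth)


def _revcomp_pwm(freq: np.ndarray) -> np.ndarray:
    return freq[::-1, ::-1]


def pwm_column_correlation(
    planted: np.ndarray, recovered: np.ndarray, shift_slack: int = 4
) -> float:
    """Best Pearson correlation between two frequency matrices.

    The matrices slide along each other in both orientations; the
    correlation is taken over the flattened 4 x k column overlap, for
    every alignment whose overlap is at least the narrower width minus
    ``shift_slack`` (discovery may report the motif a few columns
    shifted, with near-background flanks that carry no signal), and the
    maximum over offsets and strands is returned.
    """
    planted = np.asarray(planted, dtype=float)
    recovered = np.asarray(recovered, dtype=float)
    small, big = (planted, recovered) if planted.shape[1] <= recovered.shape[1] else (
        recovered,
        planted,
    )
    w_s, w_b = small.shape[1], big.shape[1]
    min_overlap = max(2, w_s - shift_slack)
    best = -1.0
    for cand in (big, _revcomp_pwm(big)):
        for off in range(-(w_s - min_overlap), w_b - min_overlap + 1):
            lo_s, hi_s = max(0, -off), min(w_s, w_b - off)
            if hi_s - lo_s < min_overlap:
                continue
            a = small[:, lo_s:hi_s].ravel()
            b = cand[:, lo_s + off : hi_s + off].ravel()
            if a.std() == 0 or b.std() == 0:
                continue
            best = max(best, float(np.corrcoef(a, b)[0, 1]))
    return best
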