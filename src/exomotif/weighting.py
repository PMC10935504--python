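"""Coverage normalisation and the strand-expanded coverage matrix.

Raw per-base ChIP-exo coverage x_i is normalised per peak as

    x_i  <-  log(1 + x_i) / max_j log(1 + x_j)

so every peak's coverage lies in [0, 1] with maximum exactly 1 (the log
base cancels in the ratio). The strand matrix interleaves each peak with
its reverse complement: row 2k is the forward sequence of peak k, row
2k+1 its reverse complement carrying the reversed coverage vector, which
is the only position-consistent assignment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import PeakRecord, _revcomp

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def reverse_complement(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}; N maps to N."""
    if set(seq) - set("ACGTN"):
        raise ValueError(f"invalid characters in sequence: {sorted(set(seq) - set('ACGTN'))}")
    return _revcomp(seq)


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as uint8 codes (A,C,G,T,N -> 0..4)."""
    return np.frombuffer(seq.translate(_ENC).encode(), dtype=np.uint8)


_ENC = str.maketrans("ACGTN", "\x00\x01\x02\x03\x04")


def normalize_coverage(raw) -> np.ndarray:
    """Apply the log-ratio normalisation to a raw coverage vector.

    All-zero input returns all zeros (the maximum in the denominator
    would be 0). Negative entries are an error.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.size and raw.min() < 0:
        raise ValueError("coverage values must be non-negative")
    logged = np.log1p(raw)
    top = logged.max(initial=0.0)
    if top == 0.0:
        return np.zeros_like(raw)
    return logged / top


@dataclass
class WeightedPeakSet:
    """m peak sequences with normalised per-base coverage in [0, 1]."""

    records: list[PeakRecord]

    def __post_init__(self) -> None:
        for rec in self.records:
            if rec.coverage is not None:
                if rec.coverage.size and (rec.coverage.min() < 0 or rec.coverage.max() > 1):
                    raise ValueError(f"record {rec.id!r}: normalised coverage outside [0,1]")

    @classmethod
    def from_records(cls, records, mode: str = "cov") -> "WeightedPeakSet":
        """Normalise raw coverage; ``mode='basic'`` discards coverage.

        Records without coverage always come out in basic style
        (coverage None), regardless of mode.
        """
        out = []
        for rec in records:
            if mode == "basic" or rec.coverage is None:
                out.append(PeakRecord(id=rec.id, sequence=rec.sequence))
            else:
                out.append(
                    PeakRecord(
                        id=rec.id,
                        sequence=rec.sequence,
                        coverage=normalize_coverage(rec.coverage),
                    )
                )
        return cls(out)

    @property
    def m(self) -> int:
        return len(self.records)

    @property
    def lengths(self) -> list[int]:
        return [len(r) for r in self.records]

    @property
    def mean_length(self) -> float:
        return float(np.mean(self.lengths))


class StrandCoverageMatrix:
    """Strand-expanded per-position coverage (the 2m-row weight matrix).

    Row 2k holds peak k's forward sequence and normalised coverage; row
    2k+1 holds the reverse complement with the reversed coverage vector.
    In basic mode (no coverage) every entry is 1.0, which turns the
    stage-1 weight f*(w_a + w_b) into a pure similarity score 2f.
    Rows may have unequal lengths; loops run per-row.
    """

    def __init__(self, peaks: WeightedPeakSet):
        self.peaks = peaks
        self.sequences: list[str] = []
        self.codes: list[np.ndarray] = []
        self.rows: list[np.ndarray] = []
        for rec in peaks.records:
            fwd = rec.sequence
            rev = reverse_complement(fwd)
            if rec.coverage is None:
                cov_f = np.ones(len(fwd))
            else:
                cov_f = np.asarray(rec.coverage, dtype=float)
            self.sequences.extend([fwd, rev])
            self.codes.extend([encode(fwd), encode(rev)])
            self.rows.extend([cov_f.copy(), cov_f[::-1].copy()])

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def row_length(self, row: int) -> int:
        return len(self.rows[row])

    def sequence_of_row(self, row: int) -> int:
        """Index of the original peak a strand row belongs to."""
        return row // 2

    def is_reverse_row(self, row: int) -> bool:
        return row % 2 == 1

    def row_normalized(self) -> list[np.ndarray]:
        """Each row divided by its maximum; all-zero rows stay zero."""
        out = []
        for row in self.rows:
            top = row.max(initial=0.0)
            out.append(row / top if top > 0 else row.copy())
        return out

    def to_forward_span(self, row: int, start: int, width: int) -> tuple[int, int, int]:
        """Map a segment on a strand row to forward-strand coordinates.

        Returns (sequence index, forward start, forward end), half-open.
        """
        seq_idx = row // 2
        n = self.row_length(row)
        if row % 2 == 0:
            return seq_idx, start, start + width
        return seq_idx, n - (start + width), n - start


def build_strand_matrix(peaks: WeightedPeakSet) -> StrandCoverageMatrix:
    """Build the 2m-row strand-expanded coverage matrix."""
    return StrandCoverageMatrix(peaks)
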