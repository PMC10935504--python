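"""Readers and writers for every external representation the pipeline touches.

Supported formats: FASTA (peaks or genome), BED3/BED6 peak intervals,
per-base coverage tracks (plain ``contig pos value`` TSV, or BigWig through
an optional adapter), the combined coverage-FASTA format that carries a
peak's sequence together with its normalised per-base coverage, and the
MEME minimal motif format for discovered PWMs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

log = logging.getLogger(__name__)

_VALID = set("ACGTN")


@dataclass
class PeakRecord:
    """One narrow peak: id, DNA sequence and (optionally) per-base coverage."""

    id: str
    sequence: str
    coverage: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        if self.coverage is not None:
            self.coverage = np.asarray(self.coverage, dtype=float)
            if len(self.coverage) != len(self.sequence):
                raise ValueError(
                    f"record {self.id!r}: coverage length {len(self.coverage)} "
                    f"!= sequence length {len(self.sequence)}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


def _clean_sequence(seq: str, *, context: str) -> str:
    """Uppercase and map IUPAC ambiguity codes other than N to N."""
    seq = seq.upper()
    if set(seq) <= _VALID:
        return seq
    bad = sorted(set(seq) - _VALID)
    for ch in bad:
        if not ch.isalpha():
            raise ValueError(f"{context}: invalid character {ch!r} in sequence")
    log.warning("%s: ambiguity codes %s mapped to N", context, bad)
    return "".join(c if c in _VALID else "N" for c in seq)


class GenomeIndex:
    """In-memory contig store with half-open interval lookups.

    Construct from a dict of contig sequences or from a FASTA file
    (``GenomeIndex.from_fasta``, backed by pyfaidx).
    """

    def __init__(self, contigs: Mapping[str, str]):
        self._contigs = {
            name: _clean_sequence(str(seq), context=f"contig {name}")
            for name, seq in contigs.items()
        }

    @classmethod
    def from_fasta(cls, path: str | Path) -> "GenomeIndex":
        from pyfaidx import Fasta

        fa = Fasta(str(path), as_raw=True, sequence_always_upper=True)
        return cls({name: str(fa[name][:]) for name in fa.keys()})

    @property
    def contigs(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self._contigs.items()}

    def __contains__(self, name: str) -> bool:
        return name in self._contigs

    def fetch(self, contig: str, start: int, end: int) -> str:
        if contig not in self._contigs:
            raise KeyError(f"unknown contig {contig!r}")
        seq = self._contigs[contig]
        if start < 0 or end > len(seq) or start >= end:
            raise ValueError(
                f"interval {contig}:{start}-{end} outside contig of length {len(seq)}"
            )
        return seq[start:end]


def read_fasta(path: str | Path) -> list[PeakRecord]:
    """Read a peak FASTA file into records without coverage.

    Multi-line sequences are concatenated and case-folded to upper.
    Duplicate ids and empty files are errors.
    """
    records: list[PeakRecord] = []
    seen: set[str] = set()
    header: str | None = None
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        seq = _clean_sequence("".join(chunks), context=f"record {header}")
        records.append(PeakRecord(id=header, sequence=seq))

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].split()[0]
                if header in seen:
                    raise ValueError(f"duplicate FASTA id {header!r}")
                seen.add(header)
                chunks = []
            else:
                if header is None:
                    raise ValueError("sequence data before first FASTA header")
                chunks.append(line)
    flush()
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[PeakRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def read_bed(path: str | Path) -> list[tuple[str, int, int, str, str]]:
    """Parse BED3/BED6 into (contig, start, end, name, strand) tuples."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: malformed BED line (<3 fields)")
            contig = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start < 0 or end <= start:
                raise ValueError(f"{path}:{lineno}: invalid interval {start}-{end}")
            name = fields[3] if len(fields) >= 4 and fields[3] != "." else ""
            strand = fields[5] if len(fields) >= 6 else "+"
            if strand not in "+-":
                raise ValueError(f"{path}:{lineno}: invalid strand {strand!r}")
            out.append((contig, start, end, name, strand))
    return out


def extract_peaks(genome: GenomeIndex, bed: str | Path) -> list[PeakRecord]:
    """Extract peak sequences for BED intervals (0-based, half-open).

    A "-" strand field yields the reverse complement. Record ids default to
    ``contig:start-end`` when the BED has no name column.
    """
    records = []
    for contig, start, end, name, strand in read_bed(bed):
        seq = genome.fetch(contig, start, end)
        if strand == "-":
            seq = _revcomp(seq)
        rec_id = name or f"{contig}:{start}-{end}"
        records.append(PeakRecord(id=rec_id, sequence=seq))
    return records


class TsvCoverageTrack:
    """Per-base coverage from a plain text file of ``contig pos value`` rows.

    Positions are 0-based. Positions absent from the file read as 0.
    """

    def __init__(self, path: str | Path):
        self._data: dict[str, dict[int, float]] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                fields = line.split()
                if len(fields) != 3:
                    raise ValueError(f"{path}:{lineno}: expected 'contig pos value'")
                contig, pos, value = fields[0], int(fields[1]), float(fields[2])
                self._data.setdefault(contig, {})[pos] = value

    def values(self, contig: str, start: int, end: int) -> np.ndarray:
        per_pos = self._data.get(contig, {})
        return np.array([per_pos.get(p, 0.0) for p in range(start, end)])


class BigWigCoverageTrack:
    """Adapter over pyBigWig for per-base coverage extraction."""

    def __init__(self, path: str | Path):
        import pyBigWig

        self._bw = pyBigWig.open(str(path))

    def values(self, contig: str, start: int, end: int) -> np.ndarray:
        if contig not in self._bw.chroms():
            return np.zeros(end - start)
        vals = np.asarray(self._bw.values(contig, start, end), dtype=float)
        return np.nan_to_num(vals, nan=0.0)


def open_coverage_track(path: str | Path):
    """Open a coverage file, dispatching on the .bw/.bigwig suffix."""
    suffix = Path(path).suffix.lower()
    if suffix in {".bw", ".bigwig"}:
        return BigWigCoverageTrack(path)
    return TsvCoverageTrack(path)


def attach_coverage(
    peaks: Sequence[PeakRecord],
    tracks,
    intervals: Sequence[tuple[str, int, int]] | None = None,
) -> list[PeakRecord]:
    """Attach raw coverage from one or more tracks to each peak.

    ``intervals`` gives the genomic (contig, start, end) of each peak; when
    omitted, the peak id is parsed as ``contig:start-end``. Multiple tracks
    are summed position-wise; positions missing from every track read as 0.
    """
    if not isinstance(tracks, (list, tuple)):
        tracks = [tracks]
    if intervals is None:
        intervals = []
        for rec in peaks:
            contig, _, span = rec.id.rpartition(":")
            try:
                start_s, end_s = span.split("-")
                intervals.append((contig, int(start_s), int(end_s)))
            except ValueError as exc:
                raise ValueError(
                    f"cannot parse interval from record id {rec.id!r}; "
                    "pass intervals explicitly"
                ) from exc
    out = []
    for rec, (contig, start, end) in zip(peaks, intervals):
        cov = np.zeros(len(rec.sequence))
        for track in tracks:
            cov += track.values(contig, start, end)
        if not cov.any():
            log.info("peak %s: no coverage in any track; zeros attached", rec.id)
        out.append(PeakRecord(id=rec.id, sequence=rec.sequence, coverage=cov))
    return out


def write_coverage_fasta(records: Iterable[PeakRecord], path: str | Path) -> None:
    """Write records in the combined coverage-FASTA dialect.

    Each record spans three lines: ``>id``, the sequence, and a ``#`` line
    of space-separated normalised per-base coverage values (6 decimals).
    Coverage must be present and already normalised into [0, 1].
    """
    with open(path, "w") as fh:
        for rec in records:
            if rec.coverage is None:
                raise ValueError(f"record {rec.id!r}: no coverage to write")
            cov = np.asarray(rec.coverage, dtype=float)
            if len(cov) != len(rec.sequence):
                raise ValueError(f"record {rec.id!r}: coverage/sequence length mismatch")
            if cov.min() < 0 or cov.max() > 1:
                raise ValueError(f"record {rec.id!r}: coverage outside [0, 1]")
            vals = " ".join(f"{v:.6f}" for v in cov)
            fh.write(f">{rec.id}\n{rec.sequence}\n# {vals}\n")


def read_coverage_fasta(path: str | Path) -> list[PeakRecord]:
    """Read the 3-line-per-record coverage-FASTA dialect."""
    records: list[PeakRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    i = 0
    while i < len(lines):
        if not lines[i].startswith(">"):
            raise ValueError(f"{path}: expected '>' header at record boundary, got {lines[i]!r}")
        rec_id = lines[i][1:].split()[0]
        if rec_id in seen:
            raise ValueError(f"duplicate id {rec_id!r}")
        seen.add(rec_id)
        if i + 2 >= len(lines) or not lines[i + 2].lstrip().startswith("#"):
            raise ValueError(f"{path}: record {rec_id!r} missing sequence or coverage line")
        seq = _clean_sequence(lines[i + 1].strip(), context=f"record {rec_id}")
        cov = np.array([float(v) for v in lines[i + 2].lstrip("# ").split()])
        if cov.size and (cov.min() < 0 or cov.max() > 1):
            raise ValueError(f"record {rec_id!r}: coverage outside [0, 1]")
        records.append(PeakRecord(id=rec_id, sequence=seq, coverage=cov))
        i += 3
    if not records:
        raise ValueError(f"no records in {path}")
    return records


def write_meme_pwm(motifs, path: str | Path, background=None) -> None:
    """Write motif models in MEME minimal format.

    ``motifs`` is a sequence of objects exposing ``name``, ``frequencies``
    (a 4 x width array of column probabilities, rows in A,C,G,T order) and
    ``nsites``. An empty list yields a valid header-only file.
    """
    motifs = list(motifs)
    if background is None:
        background = motifs[0].background if motifs else np.full(4, 0.25)
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(
            "A {:.5f} C {:.5f} G {:.5f} T {:.5f}\n".format(*np.asarray(background))
        )
        for motif in motifs:
            freq = np.asarray(motif.frequencies)
            width = freq.shape[1]
            fh.write(f"\nMOTIF {motif.name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {width} "
                f"nsites= {motif.nsites} E= 0\n"
            )
            for j in range(width):
                fh.write(" ".join(f"{freq[i, j]:.6f}" for i in range(4)) + "\n")


def read_meme_pwm(path: str | Path) -> list[tuple[str, np.ndarray, int]]:
    """Minimal MEME-format reader: returns (name, 4 x w frequencies, nsites)."""
    out = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if lines[i].startswith("MOTIF"):
            name = lines[i].split()[1]
            i += 1
            while not lines[i].startswith("letter-probability"):
                i += 1
            header = lines[i]
            width = int(header.split("w=")[1].split()[0])
            nsites = int(header.split("nsites=")[1].split()[0])
            cols = []
            for j in range(width):
                i += 1
                cols.append([float(v) for v in lines[i].split()])
            out.append((name, np.array(cols).T, nsites))
        i += 1
    return out
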