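"""Readers/writers for genomic formats and the shared interval/track data model.

All internal coordinates are 0-based half-open. samtools-depth input is
1-based (converted on read); BED output is 0-based half-open; PAF is already
0-based half-open; MUMmer show-coords is 1-based inclusive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO

__all__ = [
    "SequenceRecord",
    "Interval",
    "DepthTrack",
    "AlignmentHit",
    "read_fasta",
    "write_fasta",
    "read_depth_table",
    "write_depth_table",
    "read_bed",
    "write_bed",
    "import_alignment_hits",
]

# IUPAC nucleotide one-letter codes (plus N); U is mapped to T on read.
_IUPAC = frozenset("ACGTNRYSWKMBDHV")
_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")


@dataclass(frozen=True)
class SequenceRecord:
    """One replicon or contig: an id, a DNA sequence and a replicon role."""

    id: str
    seq: str
    role: str = "unknown"  # primary | secondary | contig | unknown

    def __post_init__(self) -> None:
        if len(self.seq) < 1:
            raise ValueError(f"empty sequence for record {self.id!r}")
        if self.role not in ("primary", "secondary", "contig", "unknown"):
            raise ValueError(f"unknown role {self.role!r}")

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def gc(self) -> float:
        """GC fraction; ambiguous bases (incl. N) are excluded from both
        numerator and denominator."""
        gc = sum(self.seq.count(b) for b in "GC")
        at = sum(self.seq.count(b) for b in "AT")
        if gc + at == 0:
            return float("nan")
        return gc / (gc + at)

    def reverse_complement(self) -> "SequenceRecord":
        return SequenceRecord(self.id, self.seq.translate(_COMPLEMENT)[::-1], self.role)


@dataclass(frozen=True, order=True)
class Interval:
    """0-based half-open interval on a named sequence."""

    seq_id: str
    start: int
    end: int
    strand: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.seq_id}:{self.start}-{self.end}"
            )
        if self.strand not in (None, "+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.seq_id == other.seq_id
            and self.start < other.end
            and other.start < self.end
        )

    def jaccard(self, other: "Interval") -> float:
        """Overlap / union length; 0 for different sequences."""
        if self.seq_id != other.seq_id:
            return 0.0
        inter = min(self.end, other.end) - max(self.start, other.start)
        if inter <= 0:
            return 0.0
        union = max(self.end, other.end) - min(self.start, other.start)
        return inter / union


@dataclass
class DepthTrack:
    """Per-position read depth along one replicon."""

    seq_id: str
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        if self.depth.ndim != 1 or self.depth.size < 1:
            raise ValueError("depth must be a non-empty 1-D array")
        if np.any(self.depth < 0):
            raise ValueError(f"negative depth on {self.seq_id}")

    @property
    def length(self) -> int:
        return int(self.depth.size)


@dataclass(frozen=True)
class AlignmentHit:
    """A local alignment between a query and a target sequence.

    `identity` = matches / alignment columns (matches + mismatches + gap
    columns). Query and target intervals are on the forward strands of their
    respective sequences; `strand` is '-' when the query aligns
    reverse-complemented.
    """

    query: Interval
    target: Interval
    identity: float
    aligned_cols: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0.0 <= self.identity <= 1.0):
            raise ValueError(f"identity {self.identity} outside [0, 1]")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def span(self) -> int:
        """Length of the aligned span (max of query/target extents)."""
        return max(len(self.query), len(self.target))


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path, role: str = "unknown") -> list[SequenceRecord]:
    """Read a multi-record FASTA file.

    Sequences are upper-cased and U is mapped to T. Raises on an empty file,
    duplicate ids, or characters outside the IUPAC nucleotide alphabet.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper().replace("U", "T")
        bad = next((i for i, c in enumerate(seq) if c not in _IUPAC), None)
        if bad is not None:
            raise ValueError(
                f"non-IUPAC character {seq[bad]!r} at position {bad + 1} "
                f"of record {rec.id!r}"
            )
        records.append(SequenceRecord(rec.id, seq, role))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Depth tables


def read_depth_table(
    path: str | Path, expected_lengths: Mapping[str, int]
) -> list[DepthTrack]:
    """Read per-base depth in samtools-depth (3-column, 1-based) or bedGraph
    (4-column, 0-based half-open) form into dense tracks.

    Positions absent from the input are depth 0 (samtools depth omits them by
    default). One track is returned per id in `expected_lengths`, in that
    order, including all-zero tracks for ids never mentioned.
    """
    arrays = {sid: np.zeros(int(n), dtype=float) for sid, n in expected_lengths.items()}
    for sid, n in expected_lengths.items():
        if n < 1:
            raise ValueError(f"expected length for {sid!r} must be >= 1")
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) == 3:
                sid, pos_s, d_s = parts
                try:
                    pos, d = int(pos_s), float(d_s)
                except ValueError as e:
                    raise ValueError(f"{path}:{lineno}: malformed row") from e
                if sid not in arrays:
                    raise ValueError(f"{path}:{lineno}: unknown sequence {sid!r}")
                if d < 0:
                    raise ValueError(f"{path}:{lineno}: negative depth {d}")
                if not (1 <= pos <= arrays[sid].size):
                    raise ValueError(
                        f"{path}:{lineno}: position {pos} outside 1..{arrays[sid].size}"
                    )
                arrays[sid][pos - 1] = d
            elif len(parts) == 4:  # bedGraph
                sid, start_s, end_s, d_s = parts
                try:
                    start, end, d = int(start_s), int(end_s), float(d_s)
                except ValueError as e:
                    raise ValueError(f"{path}:{lineno}: malformed row") from e
                if sid not in arrays:
                    raise ValueError(f"{path}:{lineno}: unknown sequence {sid!r}")
                if d < 0:
                    raise ValueError(f"{path}:{lineno}: negative depth {d}")
                if not (0 <= start < end <= arrays[sid].size):
                    raise ValueError(f"{path}:{lineno}: span outside sequence")
                arrays[sid][start:end] = d
            else:
                raise ValueError(f"{path}:{lineno}: expected 3 or 4 columns")
    return [DepthTrack(sid, arr) for sid, arr in arrays.items()]


def write_depth_table(tracks: Iterable[DepthTrack], path: str | Path) -> None:
    """Write dense tracks as samtools-depth style TSV (1-based positions).

    Zero-depth positions are omitted, matching samtools-depth output."""
    with open(path, "w") as fh:
        for track in tracks:
            (nz,) = np.nonzero(track.depth)
            for i in nz:
                d = track.depth[i]
                d_repr = int(d) if float(d).is_integer() else d
                fh.write(f"{track.seq_id}\t{i + 1}\t{d_repr}\n")


# ---------------------------------------------------------------------------
# BED


def write_bed(
    intervals: Sequence[Interval],
    path: str | Path,
    extra_columns: Sequence[Sequence] | None = None,
) -> None:
    """Write BED3(+) lines, sorted by (seq_id, start).

    `extra_columns`, if given, is one row of extra fields per interval and is
    reordered together with the intervals.
    """
    rows = list(
        zip(intervals, extra_columns if extra_columns is not None else [()] * len(intervals))
    )
    rows.sort(key=lambda r: (r[0].seq_id, r[0].start, r[0].end))
    with open(path, "w") as fh:
        for iv, extra in rows:
            fields = [iv.seq_id, str(iv.start), str(iv.end), *map(str, extra)]
            fh.write("\t".join(fields) + "\n")


def read_bed(path: str | Path) -> list[Interval]:
    intervals = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            intervals.append(Interval(parts[0], int(parts[1]), int(parts[2])))
    return intervals


# ---------------------------------------------------------------------------
# External alignment imports


def import_alignment_hits(path: str | Path, dialect: str) -> list[AlignmentHit]:
    """Import precomputed alignments from PAF or MUMmer show-coords output.

    Hits are normalized to 0-based half-open query/target intervals with
    identity as a fraction in [0, 1]. For the `coords` dialect the reference
    is taken as the target and the second sequence as the query
    (tab-separated `show-coords -T` layout, headers tolerated).
    """
    if dialect not in ("paf", "coords"):
        raise ValueError(f"unknown alignment dialect {dialect!r}")
    hits: list[AlignmentHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if dialect == "paf":
                parts = line.split("\t")
                if len(parts) < 12:
                    raise ValueError(f"{path}:{lineno}: PAF needs >= 12 columns")
                try:
                    qname, _qlen, qs, qe = parts[0], int(parts[1]), int(parts[2]), int(parts[3])
                    strand = parts[4]
                    tname, _tlen, ts, te = parts[5], int(parts[6]), int(parts[7]), int(parts[8])
                    matches, cols = int(parts[9]), int(parts[10])
                except ValueError as e:
                    raise ValueError(f"{path}:{lineno}: malformed PAF line") from e
                if strand not in "+-":
                    raise ValueError(f"{path}:{lineno}: bad strand {strand!r}")
                hits.append(
                    AlignmentHit(
                        query=Interval(qname, qs, qe),
                        target=Interval(tname, ts, te),
                        identity=matches / cols if cols else 0.0,
                        aligned_cols=cols,
                        strand=strand,
                    )
                )
            else:  # show-coords -T: S1 E1 S2 E2 LEN1 LEN2 %IDY [ref qry]
                parts = line.split("\t")
                if len(parts) < 7:
                    continue  # header / separator lines
                try:
                    s1, e1, s2, e2 = (int(p) for p in parts[:4])
                    len1, len2 = int(parts[4]), int(parts[5])
                    idy = float(parts[6])
                except ValueError:
                    if lineno <= 4:  # NUCMER header block
                        continue
                    raise ValueError(f"{path}:{lineno}: malformed coords line")
                tname = parts[7] if len(parts) > 7 else "ref"
                qname = parts[8] if len(parts) > 8 else "query"
                strand = "+" if s2 <= e2 else "-"
                qs, qe = (s2, e2) if s2 <= e2 else (e2, s2)
                hits.append(
                    AlignmentHit(
                        query=Interval(qname, qs - 1, qe),
                        target=Interval(tname, s1 - 1, e1),
                        identity=idy / 100.0,
                        aligned_cols=max(len1, len2),
                        strand=strand,
                    )
                )
    return hits
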