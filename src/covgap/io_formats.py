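"""Readers/writers for FASTA, FASTQ, SAM, BED and depth tables.

All interval arithmetic in this package uses 0-based half-open coordinates
(the BED convention).  SAM's 1-based POS is converted at parse time and
nowhere else.
"""

from __future__ import annotations

import io
import os
import tempfile
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ContigSet",
    "GenomicInterval",
    "DepthTrack",
    "ReadRecord",
    "FormatError",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "depth_from_sam",
    "read_depth_table",
    "write_depth_table",
    "write_gap_bed",
]

VALID_BASES = frozenset("ACGTN")

# uppercase, U->T, anything not ACGTN -> N
_NORMALIZE = {}
for _c in range(256):
    ch = chr(_c).upper()
    if ch == "U":
        ch = "T"
    _NORMALIZE[_c] = ch if ch in VALID_BASES else "N"
_NORMALIZE = str.maketrans(_NORMALIZE)

# byte -> 2-bit code; N and anything else -> 4
ENCODE_TABLE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    ENCODE_TABLE[_b] = _i
    ENCODE_TABLE[ord(chr(_b).lower())] = _i

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def normalize_sequence(seq: str) -> str:
    """Uppercase, map U to T, and every other non-ACGT symbol to N."""
    return seq.translate(_NORMALIZE)


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a nucleotide string as uint8 codes (A,C,G,T -> 0..3, else 4)."""
    return ENCODE_TABLE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class FormatError(ValueError):
    """A malformed input file or record."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open interval [start, end) on a named contig."""

    contig: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid interval {self.contig}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def name(self) -> str:
        return f"{self.contig}:{self.start}-{self.end}"


class ContigSet:
    """Ordered mapping of contig name -> uppercase A/C/G/T/N sequence."""

    def __init__(self, entries: Iterable[tuple[str, str]] = ()) -> None:
        self._seqs: dict[str, str] = {}
        self._encoded: dict[str, np.ndarray] = {}
        for name, seq in entries:
            self.add(name, seq)

    def add(self, name: str, seq: str) -> None:
        if not name:
            raise FormatError("contig with empty name")
        if name in self._seqs:
            raise FormatError(f"duplicate contig name: {name!r}")
        seq = normalize_sequence(seq)
        if not seq:
            raise FormatError(f"contig {name!r} has an empty sequence")
        self._seqs[name] = seq

    @property
    def names(self) -> list[str]:
        return list(self._seqs)

    def __contains__(self, name: str) -> bool:
        return name in self._seqs

    def __getitem__(self, name: str) -> str:
        return self._seqs[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._seqs)

    def __len__(self) -> int:
        return len(self._seqs)

    def items(self) -> Iterable[tuple[str, str]]:
        return self._seqs.items()

    def length(self, name: str) -> int:
        return len(self._seqs[name])

    def total_length(self) -> int:
        return sum(len(s) for s in self._seqs.values())

    def encoded(self, name: str) -> np.ndarray:
        """Cached uint8 encoding of one contig."""
        arr = self._encoded.get(name)
        if arr is None:
            arr = encode_sequence(self._seqs[name])
            self._encoded[name] = arr
        return arr

    def slice(self, interval: GenomicInterval) -> str:
        seq = self._seqs[interval.contig]
        if interval.end > len(seq):
            raise ValueError(
                f"interval {interval.name} exceeds contig length {len(seq)}"
            )
        return seq[interval.start : interval.end]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ContigSet):
            return NotImplemented
        return list(self.items()) == list(other.items())


@dataclass
class ReadRecord:
    """A sequencing read; qualities (Phred scores) are optional."""

    id: str
    sequence: str
    qualities: Optional[Sequence[int]] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.id!r} has an empty sequence")
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ValueError(f"read {self.id!r}: quality/sequence length mismatch")

    def __len__(self) -> int:
        return len(self.sequence)


class DepthTrack:
    """Per-contig, per-position read depth.

    ``genome_mean`` (the symbol *g* of the bias score) is the grand mean over
    every reference position of every contig, zero-depth positions included.
    """

    def __init__(self, depths: dict[str, np.ndarray]) -> None:
        self.depths = {name: np.asarray(a, dtype=np.int64) for name, a in depths.items()}
        for name, arr in self.depths.items():
            if arr.ndim != 1:
                raise ValueError(f"depth array for {name!r} must be 1-D")
            if (arr < 0).any():
                raise ValueError(f"negative depth on contig {name!r}")

    @classmethod
    def zeros(cls, contigs: ContigSet) -> "DepthTrack":
        return cls({n: np.zeros(contigs.length(n), dtype=np.int64) for n in contigs})

    def __getitem__(self, name: str) -> np.ndarray:
        return self.depths[name]

    def __contains__(self, name: str) -> bool:
        return name in self.depths

    @property
    def names(self) -> list[str]:
        return list(self.depths)

    def total_positions(self) -> int:
        return sum(a.size for a in self.depths.values())

    @property
    def genome_mean(self) -> float:
        total = self.total_positions()
        if total == 0:
            return 0.0
        return float(sum(int(a.sum()) for a in self.depths.values())) / total


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def read_fasta(path: str | os.PathLike) -> ContigSet:
    """Read a FASTA file into a ContigSet.

    Sequences are uppercased, U mapped to T, and any other non-ACGTN symbol
    mapped to N.  Empty files, duplicate headers and empty records raise
    :class:`FormatError` naming the offending record.
    """
    contigs = ContigSet()
    n = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        contigs.add(rec.id, str(rec.seq))
        n += 1
    if n == 0:
        raise FormatError(f"no FASTA records in {path}")
    return contigs


def write_fasta(
    records: Iterable[tuple[str, str]], path: str | os.PathLike, wrap: int = 60
) -> None:
    """Write (name, sequence) records as wrapped FASTA (deterministic bytes)."""
    seen: set[str] = set()
    with open(path, "w") as fh:
        for name, seq in records:
            if name in seen:
                raise ValueError(f"duplicate record name {name!r}")
            seen.add(name)
            fh.write(f">{name}\n")
            for i in range(0, len(seq), wrap):
                fh.write(seq[i : i + wrap])
                fh.write("\n")


def read_fastq(path: str | os.PathLike) -> list[ReadRecord]:
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        quals = rec.letter_annotations.get("phred_quality")
        reads.append(
            ReadRecord(rec.id, normalize_sequence(str(rec.seq)), quals)
        )
    return reads


def write_fastq(reads: Iterable[ReadRecord], path: str | os.PathLike) -> None:
    """Write reads as 4-line FASTQ (Phred+33); missing qualities become 'I'."""

    def _records():
        for r in reads:
            rec = SeqRecord(Seq(r.sequence), id=r.id, description="")
            quals = r.qualities if r.qualities is not None else [40] * len(r)
            rec.letter_annotations["phred_quality"] = list(quals)
            yield rec

    with open(path, "w") as fh:
        SeqIO.write(_records(), fh, "fastq")


# ---------------------------------------------------------------------------
# SAM


def _sam_has_sq_header(path: str) -> bool:
    with open(path) as fh:
        for line in fh:
            if not line.startswith("@"):
                return False
            if line.startswith("@SQ"):
                return True
    return False


def sam_header(contigs: ContigSet) -> str:
    lines = ["@HD\tVN:1.6\tSO:unknown"]
    for name in contigs:
        lines.append(f"@SQ\tSN:{name}\tLN:{contigs.length(name)}")
    return "\n".join(lines) + "\n"


def depth_from_sam(path: str | os.PathLike, contigs: ContigSet) -> DepthTrack:
    """Compute per-base depth from a SAM file.

    Reference positions consumed by CIGAR M/=/X each gain one depth unit per
    aligned read; clips and insertions contribute nothing; D/N consume
    reference without adding depth.  A headerless SAM is accepted: an @SQ
    header is synthesized from ``contigs`` so pysam can parse it.
    """
    import pysam

    path = str(path)
    track = DepthTrack.zeros(contigs)
    tmp = None
    try:
        if not _sam_has_sq_header(path):
            fd, tmp = tempfile.mkstemp(suffix=".sam")
            with os.fdopen(fd, "w") as out, open(path) as src:
                out.write(sam_header(contigs))
                for line in src:
                    if not line.startswith("@"):
                        out.write(line)
            sam_path = tmp
        else:
            sam_path = path
        with pysam.AlignmentFile(sam_path, "r", check_sq=False) as sam:
            for aln in sam:
                if aln.is_unmapped or aln.cigartuples is None:
                    continue
                rname = aln.reference_name
                if rname not in contigs:
                    raise FormatError(
                        f"read {aln.query_name!r} aligned to unknown contig {rname!r}"
                    )
                arr = track[rname]
                pos = aln.reference_start
                for op, length in aln.cigartuples:
                    if op in (0, 7, 8):  # M, =, X
                        if pos + length > arr.size:
                            raise FormatError(
                                f"read {aln.query_name!r}: CIGAR extends past "
                                f"the end of contig {rname!r}"
                            )
                        arr[pos : pos + length] += 1
                        pos += length
                    elif op in (2, 3):  # D, N consume reference only
                        pos += length
                        if pos > arr.size:
                            raise FormatError(
                                f"read {aln.query_name!r}: CIGAR extends past "
                                f"the end of contig {rname!r}"
                            )
                    # I, S, H, P consume no reference
    finally:
        if tmp is not None:
            os.unlink(tmp)
    return track


# ---------------------------------------------------------------------------
# depth tables and BED


def write_depth_table(track: DepthTrack, path: str | os.PathLike) -> None:
    """TSV with columns contig / position (0-based) / depth, one row per base."""
    with open(path, "w") as fh:
        fh.write("contig\tposition\tdepth\n")
        for name in track.names:
            arr = track[name]
            buf = io.StringIO()
            for i, d in enumerate(arr):
                buf.write(f"{name}\t{i}\t{d}\n")
            fh.write(buf.getvalue())


def read_depth_table(path: str | os.PathLike, contigs: ContigSet) -> DepthTrack:
    """Read the contig/position/depth TSV; missing positions stay at 0."""
    track = DepthTrack.zeros(contigs)
    with open(path) as fh:
        first = fh.readline()
        if first and not first.startswith("contig\t"):
            fh.seek(0)
        for ln, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3:
                raise FormatError(f"{path}: malformed depth row at line {ln}")
            name, pos, depth = parts[0], int(parts[1]), int(parts[2])
            if name not in track:
                raise FormatError(f"{path}: unknown contig {name!r} at line {ln}")
            track[name][pos] = depth
    return track


def write_gap_bed(gaps: Sequence, path: str | os.PathLike) -> None:
    """BED5 of coverage gaps: contig, start, end, name, bias (4 decimals).

    Rows are sorted by (contig, start); coordinates are 0-based half-open.
    """
    rows = sorted(gaps, key=lambda g: (g.interval.contig, g.interval.start))
    with open(path, "w") as fh:
        for i, gap in enumerate(rows, start=1):
            if gap.bias is None:
                raise ValueError(f"gap {gap.interval.name} has no bias score")
            iv = gap.interval
            fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\tgap_{i}\t{gap.bias:.4f}\n")
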