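"""Built-in local read mapper: k-mer seeding plus banded local extension.

The mapper exists so the whole pipeline runs at desk scale without an
external aligner; externally produced SAM bypasses it.  Local semantics
matter: a read whose tail continues into sequence absent from the reference
is soft-clipped, so per-base depth stops exactly at the junction — the
signal the gap caller depends on.

Layout: sequences are 2-bit encoded (N = 4); all contigs are concatenated
into one array with per-contig global offsets; k-mer codes over the
concatenation are sorted once, and lookups are binary searches.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import edlib
import numpy as np

from .io_formats import (
    ContigSet,
    DepthTrack,
    ReadRecord,
    encode_sequence,
    reverse_complement,
    sam_header,
)

__all__ = [
    "SeedIndex",
    "AlignmentPlacement",
    "build_index",
    "map_read",
    "depth_from_reads",
    "placements_to_sam",
]

MIN_K = 11

_CIG_EXT = re.compile(r"(\d+)([=XIDM])")
_CIG_ALL = re.compile(r"(\d+)([=XIDMS])")


@dataclass
class AlignmentPlacement:
    """One local placement of a read on the reference.

    ``read_start``/``read_end`` delimit the aligned portion of the read as
    given to the mapper (soft-clipped ends excluded); for minus-strand
    placements they refer to the reverse-complemented read.
    """

    read_id: str
    contig: str
    ref_start: int
    ref_end: int
    read_start: int
    read_end: int
    edit_distance: int
    cigar: str
    strand: str = "+"

    @property
    def aligned_length(self) -> int:
        return self.read_end - self.read_start


class SeedIndex:
    """Sorted-array index of every exact k-mer position of a ContigSet."""

    def __init__(self, contigs: ContigSet, k: int = 17) -> None:
        if k < MIN_K:
            raise ValueError(f"seed length k={k} below minimum {MIN_K}")
        self.k = k
        self.contigs = contigs
        self.contig_names = contigs.names
        lengths = np.array([contigs.length(n) for n in self.contig_names], dtype=np.int64)
        # one N spacer between contigs so no k-mer spans a boundary
        self.offsets = np.zeros(len(lengths), dtype=np.int64)
        if len(lengths) > 1:
            self.offsets[1:] = np.cumsum(lengths[:-1] + 1)
        total = int(lengths.sum()) + max(0, len(lengths) - 1)
        self.genome = np.full(total, 4, dtype=np.uint8)
        for name, off, ln in zip(self.contig_names, self.offsets, lengths):
            self.genome[off : off + ln] = contigs.encoded(name)
        self.lengths = lengths
        self._pow4 = (4 ** np.arange(k, dtype=np.uint64)).astype(np.uint64)
        codes, valid = self._codes(self.genome)
        pos = np.flatnonzero(valid)
        codes = codes[pos]
        order = np.argsort(codes, kind="stable")
        self.sorted_codes = codes[order]
        self.sorted_pos = pos[order].astype(np.int64)

    def _codes(self, enc: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """All k-mer codes of an encoded array and their validity (no N)."""
        k = self.k
        if enc.size < k:
            return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
        win = np.lib.stride_tricks.sliding_window_view(enc, k)
        codes = win.astype(np.uint64) @ self._pow4
        has_n = np.convolve((enc == 4).astype(np.int32), np.ones(k, dtype=np.int32))[
            k - 1 : enc.size
        ]
        return codes, has_n == 0

    def n_kmers(self) -> int:
        return int(self.sorted_codes.size)

    def lookup(self, code: int) -> np.ndarray:
        """Global positions of one k-mer code."""
        code = np.uint64(code)  # python-int needles hit a numpy slow path
        lo = np.searchsorted(self.sorted_codes, code, side="left")
        hi = np.searchsorted(self.sorted_codes, code, side="right")
        return self.sorted_pos[lo:hi]

    def contig_of(self, gpos: int) -> int:
        """Index of the contig containing a global position."""
        return int(np.searchsorted(self.offsets, gpos, side="right")) - 1

    def read_codes(self, enc: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return self._codes(enc)


def build_index(contigs: ContigSet, k: int = 17) -> SeedIndex:
    return SeedIndex(contigs, k=k)


def _best_segment(match: np.ndarray, mismatch_penalty: float = 3.0) -> tuple[int, int]:
    """Max-scoring contiguous segment under +1 match / -penalty mismatch.

    Returns half-open (a, b) in the coordinate of ``match``; (0, 0) when no
    positive-scoring segment exists.
    """
    score = np.where(match, 1.0, -mismatch_penalty)
    prefix = np.concatenate(([0.0], np.cumsum(score)))
    running_min = np.minimum.accumulate(prefix)
    gains = prefix[1:] - running_min[:-1]
    b = int(np.argmax(gains)) + 1
    if gains[b - 1] <= 0:
        return 0, 0
    a = int(np.argmin(prefix[:b]))
    return a, b


def _evaluate_candidate(
    seq: str,
    enc: np.ndarray,
    index: SeedIndex,
    contig_idx: int,
    dstart: int,
    max_edit_frac: float,
) -> Optional[tuple]:
    """Score one candidate diagonal; returns
    (edit, -aligned_len, contig_idx, ref_start, read_a, read_b, cigar)."""
    clen = int(index.lengths[contig_idx])
    off = int(index.offsets[contig_idx])
    L = len(seq)
    ref_lo = max(0, dstart)
    ref_hi = min(clen, dstart + L)
    if ref_hi - ref_lo < 1:
        return None
    ra, rb = ref_lo - dstart, ref_hi - dstart
    ref_slice = index.genome[off + ref_lo : off + ref_hi]
    read_slice = enc[ra:rb]
    match = (ref_slice == read_slice) & (read_slice != 4) & (ref_slice != 4)
    if rb - ra == L and match.all():
        return (0, -L, contig_idx, ref_lo, 0, L, f"{L}M")
    a, b = _best_segment(match)
    if b - a < max(index.k, L * 0.5):
        return None
    a += ra
    b += ra
    # refine with edlib to pick up indels and the exact boundary
    pad = 8
    t_lo = max(0, dstart + a - pad)
    t_hi = min(clen, dstart + b + pad)
    contig_name = index.contig_names[contig_idx]
    target = index.contigs[contig_name][t_lo:t_hi]
    res = edlib.align(seq[a:b], target, mode="HW", task="path")
    dist = res["editDistance"]
    if dist < 0 or dist > max_edit_frac * (b - a):
        return None
    loc = res["locations"][0]
    ref_start = t_lo + loc[0]
    cigar = _normalize_cigar(res["cigar"])
    return (dist, -(b - a), contig_idx, ref_start, a, b, cigar)


def _normalize_cigar(ext_cigar: str) -> str:
    """Collapse edlib's extended CIGAR (=/X) to M/I/D runs."""
    out: list[tuple[int, str]] = []
    for n, op in _CIG_EXT.findall(ext_cigar):
        op = "M" if op in "=XM" else op
        if out and out[-1][1] == op:
            out[-1] = (out[-1][0] + int(n), op)
        else:
            out.append((int(n), op))
    return "".join(f"{n}{op}" for n, op in out)


def _map_encoded(
    read_id: str,
    seq: str,
    enc: np.ndarray,
    index: SeedIndex,
    max_edit_frac: float,
    max_hits_per_seed: int = 64,
    max_candidates: int = 64,
) -> Optional[AlignmentPlacement]:
    k = index.k
    L = len(seq)
    if L < k:
        return None
    codes, valid = index.read_codes(enc)
    stride = max(1, k // 3)
    offs = list(range(0, L - k + 1, stride))
    if offs[-1] != L - k:
        offs.append(L - k)
    diags: set[tuple[int, int]] = set()
    for o in offs:
        if not valid[o]:
            continue
        hits = index.lookup(int(codes[o]))
        if hits.size == 0 or hits.size > max_hits_per_seed:
            continue
        for p in hits:
            ci = index.contig_of(int(p))
            diags.add((ci, int(p) - o - int(index.offsets[ci])))
    if not diags:
        return None
    best: Optional[tuple] = None
    for ci, dstart in sorted(diags)[:max_candidates]:
        cand = _evaluate_candidate(seq, enc, index, ci, dstart, max_edit_frac)
        if cand is not None and (best is None or cand < best):
            best = cand
    if best is None:
        return None
    dist, neg_len, ci, ref_start, a, b, core = best
    parts = []
    if a > 0:
        parts.append(f"{a}S")
    parts.append(core)
    if L - b > 0:
        parts.append(f"{L - b}S")
    ref_span = sum(int(n) for n, op in _CIG_EXT.findall(core) if op in "MD=X")
    return AlignmentPlacement(
        read_id=read_id,
        contig=index.contig_names[ci],
        ref_start=ref_start,
        ref_end=ref_start + ref_span,
        read_start=a,
        read_end=b,
        edit_distance=dist,
        cigar="".join(parts),
    )


def map_read(
    read: ReadRecord,
    index: SeedIndex,
    contigs: ContigSet | None = None,
    max_edit_frac: float = 0.1,
    try_reverse: bool = True,
) -> Optional[AlignmentPlacement]:
    """Best local placement of a read, or None when unmapped.

    Candidates are seeded by exact k-mer hits; each candidate locus gets a
    diagonal max-scoring-segment extension (soft-clipping read ends that do
    not belong), then an edlib refinement that allows indels.  The winner is
    the qualifying placement with minimal edit distance, ties broken by
    longer aligned span, then (contig order, lowest start).  Reads shorter
    than k are unmapped by definition.
    """
    seq = read.sequence
    fwd = _map_encoded(read.id, seq, encode_sequence(seq), index, max_edit_frac)
    if fwd is not None:
        return fwd
    if try_reverse:
        rc = reverse_complement(seq)
        rev = _map_encoded(read.id, rc, encode_sequence(rc), index, max_edit_frac)
        if rev is not None:
            rev.strand = "-"
            return rev
    return None


def _add_cigar_depth(diff: np.ndarray, pos: int, cigar: str) -> None:
    for n, op in _CIG_ALL.findall(cigar):
        n = int(n)
        if op in "M=X":
            diff[pos] += 1
            diff[pos + n] -= 1
            pos += n
        elif op == "D":
            pos += n
        # I and S consume no reference


@dataclass
class MappingStats:
    total: int = 0
    mapped: int = 0
    unmapped: int = 0
    too_short: int = 0
    fast_path: int = 0


def depth_from_reads(
    reads: Sequence[ReadRecord],
    contigs: ContigSet,
    index: SeedIndex | None = None,
    k: int = 17,
    max_edit_frac: float = 0.1,
    collect_placements: bool = False,
) -> tuple[DepthTrack, MappingStats, list[AlignmentPlacement]]:
    """Map every read and accumulate per-base depth over aligned portions.

    A vectorized fast path resolves reads that match the reference exactly
    and uniquely (checked on both strands); the remainder goes through
    :func:`map_read`.  Depth counts M/=/X reference columns only, matching
    :func:`covgap.io_formats.depth_from_sam`.
    """
    if index is None:
        index = build_index(contigs, k=k)
    stats = MappingStats(total=len(reads))
    placements: list[AlignmentPlacement] = []
    diffs = {
        n: np.zeros(contigs.length(n) + 1, dtype=np.int64) for n in contigs
    }

    pending = list(range(len(reads)))
    seqs = [reads[i].sequence for i in pending]

    for attempt in ("+", "-"):
        if not pending:
            break
        exact, still = _exact_pass(seqs, index)
        for j, gstart in exact:
            i = pending[j]
            L = len(seqs[j])
            ci = index.contig_of(gstart)
            start = gstart - int(index.offsets[ci])
            name = index.contig_names[ci]
            diffs[name][start] += 1
            diffs[name][start + L] -= 1
            stats.mapped += 1
            stats.fast_path += 1
            if collect_placements:
                placements.append(
                    AlignmentPlacement(
                        reads[i].id, name, start, start + L, 0, L, 0,
                        f"{L}M", strand=attempt,
                    )
                )
        pending = [pending[j] for j in still]
        seqs = [seqs[j] for j in still]
        if attempt == "+":
            seqs = [reverse_complement(s) for s in seqs]

    for i, rc_seq in zip(pending, seqs):
        read = reads[i]
        if len(read) < index.k:
            stats.too_short += 1
            stats.unmapped += 1
            continue
        pl = map_read(read, index, contigs, max_edit_frac=max_edit_frac)
        if pl is None:
            stats.unmapped += 1
            continue
        stats.mapped += 1
        _add_cigar_depth(diffs[pl.contig], pl.ref_start, pl.cigar)
        if collect_placements:
            placements.append(pl)

    track = DepthTrack({n: np.cumsum(d[:-1]) for n, d in diffs.items()})
    return track, stats, placements


def _exact_pass(seqs: list[str], index: SeedIndex) -> tuple[list, list]:
    """Vectorized exact-and-unique placement for a batch of reads.

    Returns ([(batch_idx, global_start), ...], [unresolved batch indices]).
    A read qualifies when its first k-mer is valid, hits exactly one locus,
    and the whole read matches the reference there byte-for-byte.
    """
    k = index.k
    exact: list[tuple[int, int]] = []
    still: list[int] = []
    if not seqs:
        return exact, still
    genome = index.genome
    n = len(seqs)
    codes = np.zeros(n, dtype=np.uint64)
    encs: list[Optional[np.ndarray]] = [None] * n
    ok = np.zeros(n, dtype=bool)
    for j, s in enumerate(seqs):
        if len(s) < k:
            continue
        enc = encode_sequence(s)
        if (enc[:k] == 4).any():
            continue
        encs[j] = enc
        codes[j] = enc[:k].astype(np.uint64) @ index._pow4
        ok[j] = True
    lo = np.searchsorted(index.sorted_codes, codes, side="left")
    hi = np.searchsorted(index.sorted_codes, codes, side="right")
    unique = ok & (hi - lo == 1)
    for j in range(n):
        if not unique[j]:
            still.append(j)
            continue
        g = int(index.sorted_pos[lo[j]])
        enc = encs[j]
        L = enc.size
        # spacers between contigs are N (code 4), so the compare below also
        # fails across a contig boundary
        if (
            g + L <= genome.size
            and not (enc == 4).any()
            and np.array_equal(genome[g : g + L], enc)
        ):
            exact.append((j, g))
        else:
            still.append(j)
    return exact, still


def placements_to_sam(
    placements: Iterable[AlignmentPlacement],
    reads_by_id: dict[str, ReadRecord],
    contigs: ContigSet,
    path: str,
) -> None:
    """Emit placements as a minimal headered SAM file."""
    with open(path, "w") as fh:
        fh.write(sam_header(contigs))
        for pl in placements:
            read = reads_by_id[pl.read_id]
            seq = read.sequence
            flag = 0
            if pl.strand == "-":
                seq = reverse_complement(seq)
                flag = 16
            fh.write(
                f"{pl.read_id}\t{flag}\t{pl.contig}\t{pl.ref_start + 1}\t60\t"
                f"{pl.cigar}\t*\t0\t0\t{seq}\t*\tNM:i:{pl.edit_distance}\n"
            )
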