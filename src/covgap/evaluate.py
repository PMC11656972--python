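"""Score a pipeline run against simulated ground truth.

A truth locus counts as detected (TP) when at least ``min_overlap`` of its
length is covered by reported gap intervals (cluster members or
non-repetitive records).  A repetitive cluster none of whose members touches
any truth locus is a repetitive false positive (FP_r); a non-repetitive
record touching no truth locus is FP_nr.  One locus yields at most one TP,
however fragmented its detection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .clustering import GapCluster, semiglobal_identity
from .gaps import CoverageGap
from .io_formats import GenomicInterval
from .simulate import TruthSet

__all__ = [
    "ValidationMetrics",
    "match_truth",
    "percent_identity",
    "metrics_row",
]

_ANCHOR_K = 15


@dataclass
class ValidationMetrics:
    """One validation-table row: TP, the two FP classes, and consensus quality."""

    tp: int
    fp_nr: int
    fp_r: int
    consensus_length: int
    similarity_pct: float

    def __post_init__(self) -> None:
        if min(self.tp, self.fp_nr, self.fp_r, self.consensus_length) < 0:
            raise ValueError("negative metric")
        if not 0 <= self.similarity_pct <= 100:
            raise ValueError("similarity out of range")


def _overlap(a: GenomicInterval, b: GenomicInterval) -> int:
    if a.contig != b.contig:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def _covered_fraction(locus: GenomicInterval, intervals: Sequence[GenomicInterval]) -> float:
    """Fraction of the locus covered by the union of intervals."""
    spans = sorted(
        (max(locus.start, iv.start), min(locus.end, iv.end))
        for iv in intervals
        if iv.contig == locus.contig and iv.start < locus.end and iv.end > locus.start
    )
    covered = 0
    cur_s = cur_e = None
    for s, e in spans:
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                covered += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        covered += cur_e - cur_s
    return covered / len(locus)


def match_truth(
    clusters: Sequence[GapCluster],
    non_repetitive: Sequence[CoverageGap],
    truth: TruthSet,
    min_overlap: float = 0.5,
) -> tuple[int, int, int]:
    """(TP, FP_r, FP_nr) under the fractional-overlap matching rule."""
    reported = [g.interval for c in clusters for g in c.members]
    reported += [g.interval for g in non_repetitive]
    tp = sum(
        1 for locus in truth.loci if _covered_fraction(locus, reported) >= min_overlap
    )
    fp_r = sum(
        1
        for c in clusters
        if not any(
            _overlap(g.interval, locus) > 0
            for g in c.members
            for locus in truth.loci
        )
    )
    fp_nr = sum(
        1
        for g in non_repetitive
        if not any(_overlap(g.interval, locus) > 0 for locus in truth.loci)
    )
    return tp, fp_r, fp_nr


def _shared_kmer(a: str, b: str, k: int = _ANCHOR_K) -> bool:
    if len(a) < k or len(b) < k:
        return a in b or b in a
    kmers = {a[i : i + k] for i in range(len(a) - k + 1)}
    from .io_formats import reverse_complement

    for seq in (b, reverse_complement(b)):
        for i in range(len(seq) - k + 1):
            if seq[i : i + k] in kmers:
                return True
    return False


def percent_identity(consensus: str, true_insert: str) -> float:
    """Percent identity of the best alignment of the shorter into the longer.

    Sequences sharing no 15-mer on either strand score 0 (no qualifying
    alignment); terminal truncation of the consensus does not reduce the
    identity, matching local-alignment semantics.
    """
    if not consensus or not true_insert:
        raise ValueError("empty sequence")
    if not _shared_kmer(consensus, true_insert):
        return 0.0
    ident, _ = semiglobal_identity(consensus, true_insert)
    return ident


def metrics_row(
    clusters: Sequence[GapCluster],
    non_repetitive: Sequence[CoverageGap],
    truth: TruthSet,
    min_overlap: float = 0.5,
) -> ValidationMetrics:
    """Full validation row; consensus stats come from the cluster whose
    members overlap the most truth loci."""
    tp, fp_r, fp_nr = match_truth(clusters, non_repetitive, truth, min_overlap)
    best: Optional[GapCluster] = None
    best_hits = 0
    for c in clusters:
        hits = sum(
            1
            for g in c.members
            if any(_overlap(g.interval, locus) > 0 for locus in truth.loci)
        )
        if hits > best_hits:
            best, best_hits = c, hits
    if best is None or best.consensus is None:
        return ValidationMetrics(tp, fp_nr, fp_r, 0, 0.0)
    sim = percent_identity(best.consensus.sequence, truth.insert_sequence)
    return ValidationMetrics(tp, fp_nr, fp_r, best.consensus.length, sim)
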