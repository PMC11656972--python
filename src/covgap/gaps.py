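"""Coverage-gap detection, merging, length filtering, bias scoring, extraction.

A coverage gap is a maximal run of reference positions whose depth is at or
below a threshold (default 0, i.e. zero coverage) when the reads of sample A
are aligned to the assembly of sample P.  Each retained gap receives a
coverage-bias score

    bias = 2 * f / (g + f) - 1

where f is the mean depth over the windows flanking the gap (10 kb on each
side by default, truncated at contig ends) and g the genome-wide mean depth.
bias = 0 means the flanks look like the genomic average (a trustworthy
candidate); values near -1 or +1 flag regions of strongly depressed or
inflated flanking coverage such as telomeres.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .io_formats import ContigSet, DepthTrack, GenomicInterval

__all__ = [
    "CoverageGap",
    "GapParams",
    "BiasUndefinedError",
    "detect_gaps",
    "merge_gaps",
    "filter_by_length",
    "bias_score",
    "gap_bias",
    "extract_sequences",
]


class BiasUndefinedError(ValueError):
    """Raised when both the flank mean and the genome mean are zero."""


@dataclass
class GapParams:
    """Tunables of the gap caller.

    depth_threshold: positions with depth <= threshold are "in a gap".
    merge_distance:  gaps on the same contig separated by <= d bases merge.
    min_length:      retained gaps must span >= min_length bases (inclusive).
    flank:           window size on each side for the bias score.
    """

    depth_threshold: int = 0
    merge_distance: int = 100
    min_length: int = 1000
    flank: int = 10_000

    def __post_init__(self) -> None:
        for name in ("depth_threshold", "merge_distance", "min_length", "flank"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class CoverageGap:
    interval: GenomicInterval
    sequence: str
    bias: Optional[float] = None
    flank_mean: Optional[float] = None

    def __post_init__(self) -> None:
        if self.sequence and len(self.sequence) != len(self.interval):
            raise ValueError(
                f"gap {self.interval.name}: sequence length "
                f"{len(self.sequence)} != interval span {len(self.interval)}"
            )
        if self.bias is not None and not -1.0 <= self.bias <= 1.0:
            raise ValueError(f"bias {self.bias} outside [-1, 1]")

    @property
    def name(self) -> str:
        return self.interval.name


def detect_gaps(depth: DepthTrack, threshold: int = 0) -> list[GenomicInterval]:
    """Maximal runs of consecutive positions with depth <= threshold.

    Results are sorted by (contig, start); contig order follows the track.
    """
    out: list[GenomicInterval] = []
    for name in depth.names:
        arr = depth[name]
        mask = arr <= threshold
        if not mask.any():
            continue
        padded = np.concatenate(([False], mask, [False]))
        edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
        starts, ends = edges[0::2], edges[1::2]
        out.extend(GenomicInterval(name, int(s), int(e)) for s, e in zip(starts, ends))
    return sorted(out, key=lambda iv: (iv.contig, iv.start))


def merge_gaps(intervals: Sequence[GenomicInterval], d: int) -> list[GenomicInterval]:
    """Merge same-contig gaps whose separation (next.start - prev.end) <= d.

    Input must be sorted and non-overlapping; d = 0 merges touching intervals
    only.  Idempotent, and monotone in d.
    """
    merged: list[GenomicInterval] = []
    prev = None
    for iv in intervals:
        if prev is not None and (iv.contig, iv.start) < (prev.contig, prev.start):
            raise ValueError("merge_gaps requires sorted input")
        if (
            prev is not None
            and iv.contig == prev.contig
            and iv.start - prev.end <= d
        ):
            if iv.start < prev.end:
                raise ValueError("merge_gaps requires non-overlapping input")
            prev = GenomicInterval(prev.contig, prev.start, max(prev.end, iv.end))
            merged[-1] = prev
        else:
            merged.append(iv)
            prev = iv
    return merged


def filter_by_length(
    intervals: Sequence[GenomicInterval], min_length: int = 1000
) -> list[GenomicInterval]:
    """Keep intervals spanning at least min_length bases (inclusive)."""
    return [iv for iv in intervals if len(iv) >= min_length]


def bias_score(f: float, g: float) -> float:
    """The coverage-bias statistic 2f/(g+f) - 1; bounded in [-1, 1]."""
    if f < 0 or g < 0:
        raise ValueError("coverages must be non-negative")
    if f == 0 and g == 0:
        raise BiasUndefinedError("bias undefined: f = g = 0")
    return 2.0 * f / (g + f) - 1.0


def gap_bias(
    interval: GenomicInterval, depth: DepthTrack, flank: int = 10_000
) -> tuple[float, float]:
    """Bias score of one gap; returns (bias, flank_mean).

    f is the mean depth over up to ``flank`` positions on each side of the
    gap, truncated at contig boundaries; windows of zero usable length
    contribute no positions.  g is the genome-wide mean.  Raises
    :class:`BiasUndefinedError` when g = 0 and f = 0 (no reads at all).
    """
    arr = depth[interval.contig]
    left = arr[max(0, interval.start - flank) : interval.start]
    right = arr[interval.end : interval.end + flank]
    n = left.size + right.size
    f = float(left.sum() + right.sum()) / n if n else 0.0
    g = depth.genome_mean
    return bias_score(f, g), f


def extract_sequences(
    intervals: Sequence[GenomicInterval],
    contigs: ContigSet,
    depth: Optional[DepthTrack] = None,
    flank: int = 10_000,
) -> list[CoverageGap]:
    """Attach assembly subsequences (and bias scores, if depth given) to gaps."""
    gaps = []
    for iv in sorted(intervals, key=lambda i: (i.contig, i.start)):
        seq = contigs.slice(iv)
        bias = flank_mean = None
        if depth is not None:
            bias, flank_mean = gap_bias(iv, depth, flank=flank)
        gaps.append(CoverageGap(iv, seq, bias=bias, flank_mean=flank_mean))
    return gaps
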