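"""Similarity clustering of gap sequences.

Gap sequences are compared all-vs-all; pairs passing the identity and
coverage thresholds are edges of a similarity graph, and its connected
components (single linkage) are the clusters.  Groups of at least
``min_members`` (default 3) sequences become repetitive candidates; every
other gap is reported as non-repetitive.

The pairwise comparison aligns the full shorter sequence against the best
infix of the longer one (both strands, via edlib), which matches local
semantics for near-complete element copies; a shared-15-mer prefilter
prunes unrelated pairs before any alignment.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import median
from typing import Optional, Sequence

import edlib
import networkx as nx

from .gaps import CoverageGap
from .io_formats import reverse_complement

__all__ = [
    "SimilarityEdge",
    "GapCluster",
    "semiglobal_identity",
    "pairwise_hits",
    "connected_components",
    "partition_repetitive",
]

PREFILTER_K = 15


@dataclass
class SimilarityEdge:
    query: int
    subject: int
    identity: float  # percent, over alignment columns
    aln_len: int
    coverage: float  # fraction of the shorter sequence aligned

    def __post_init__(self) -> None:
        if self.query == self.subject:
            raise ValueError("self edge")
        if not 0 <= self.identity <= 100 or not 0 <= self.coverage <= 1:
            raise ValueError("identity/coverage out of bounds")


@dataclass
class GapCluster:
    members: list[CoverageGap]
    cluster_id: int = 0
    consensus: Optional["ConsensusRecord"] = None  # noqa: F821 (set later)

    @property
    def copy_number(self) -> int:
        return len(self.members)

    @property
    def mean_length(self) -> float:
        return sum(len(g.interval) for g in self.members) / len(self.members)

    @property
    def median_bias(self) -> float:
        return float(median(g.bias for g in self.members))


def _kmer_set(seq: str, k: int = PREFILTER_K) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def _align_stats(query: str, target: str) -> Optional[tuple[float, int]]:
    """(percent identity, alignment columns) of query vs best infix of target."""
    res = edlib.align(query, target, mode="HW", task="locations")
    dist = res["editDistance"]
    if dist < 0:
        return None
    # columns >= len(query); approximate with the target span when available
    loc = res.get("locations")
    cols = len(query)
    if loc:
        span = loc[0][1] - loc[0][0] + 1
        cols = max(cols, span)
    ident = 100.0 * (cols - dist) / cols
    return max(0.0, ident), cols


def semiglobal_identity(a: str, b: str, both_strands: bool = True) -> tuple[float, int]:
    """Best percent identity between two sequences (shorter into longer).

    Tries forward and reverse-complement orientations; returns
    (identity_pct, alignment_columns).  (0.0, 0) when alignment fails.
    """
    q, t = (a, b) if len(a) <= len(b) else (b, a)
    best = (0.0, 0)
    stats = _align_stats(q, t)
    if stats is not None and stats[0] > best[0]:
        best = stats
    if both_strands:
        stats = _align_stats(reverse_complement(q), t)
        if stats is not None and stats[0] > best[0]:
            best = stats
    return best


def pairwise_hits(
    seqs: Sequence[str],
    min_identity: float = 80.0,
    min_cov: float = 0.5,
    prefilter: bool = True,
) -> list[SimilarityEdge]:
    """Similarity edges between all pairs of sequences (both strands).

    An edge is emitted when percent identity >= min_identity and the aligned
    span covers >= min_cov of the shorter sequence.  The shared-k-mer
    prefilter skips alignment of pairs sharing no 15-mer on either strand;
    such pairs cannot reach 80% identity over a kilobase-scale sequence.
    """
    if not seqs:
        raise ValueError("pairwise_hits needs at least one sequence")
    n = len(seqs)
    kmers = None
    if prefilter:
        kmers = [_kmer_set(s) | _kmer_set(reverse_complement(s)) for s in seqs]
    edges: list[SimilarityEdge] = []
    for i in range(n):
        for j in range(i + 1, n):
            if kmers is not None and not (kmers[i] & kmers[j]):
                continue
            ident, cols = semiglobal_identity(seqs[i], seqs[j])
            if cols == 0:
                continue
            short = min(len(seqs[i]), len(seqs[j]))
            coverage = 1.0  # the full shorter sequence participates
            if ident >= min_identity and short * min_cov <= cols:
                edges.append(SimilarityEdge(i, j, ident, cols, coverage))
    return edges


def connected_components(
    edges: Sequence[SimilarityEdge], n_seqs: int
) -> list[list[int]]:
    """Single-linkage groups: connected components of the similarity graph.

    Isolated vertices are singleton groups; groups are ordered by their
    smallest member index, members ascending.
    """
    g = nx.Graph()
    g.add_nodes_from(range(n_seqs))
    for e in edges:
        if e.query >= n_seqs or e.subject >= n_seqs:
            raise ValueError("edge endpoint out of range")
        g.add_edge(e.query, e.subject)
    comps = [sorted(c) for c in nx.connected_components(g)]
    return sorted(comps, key=lambda c: c[0])


def partition_repetitive(
    groups: Sequence[Sequence[int]],
    gaps: Sequence[CoverageGap],
    min_members: int = 3,
) -> tuple[list[GapCluster], list[CoverageGap]]:
    """Split groups into repetitive clusters (size >= min_members) and the rest.

    Every gap lands in exactly one output.  Cluster ids are assigned in group
    order (1-based).
    """
    seen: set[int] = set()
    clusters: list[GapCluster] = []
    non_repetitive: list[CoverageGap] = []
    for group in groups:
        for idx in group:
            if idx in seen:
                raise ValueError(f"gap index {idx} appears in two groups")
            seen.add(idx)
        if len(group) >= min_members:
            clusters.append(
                GapCluster([gaps[i] for i in group], cluster_id=len(clusters) + 1)
            )
        else:
            non_repetitive.extend(gaps[i] for i in group)
    if len(seen) != len(gaps):
        raise ValueError("groups do not partition the gap indices")
    return clusters, non_repetitive
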