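"""Progressive multiple sequence alignment and majority-rule consensus.

Cluster members are typically near-identical copies of one element, so a
guide tree from fractional shared-k-mer distances followed by progressive
profile-profile alignment (affine gaps: match +1, mismatch -1, open -2,
extend -0.5) recovers the obvious alignment quickly and deterministically.

The consensus applies a simple majority rule per column: if the gap
character holds a strict majority the column is dropped; otherwise the most
frequent base wins, ties broken in the fixed order A < C < G < T, and N
never outvotes a base.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import linkage

from ._profile_align import align_profiles
from .clustering import GapCluster
from .io_formats import ContigSet, GenomicInterval

__all__ = [
    "MultipleAlignment",
    "ConsensusRecord",
    "progressive_msa",
    "majority_consensus",
    "cluster_summary",
    "build_cluster_consensus",
    "refine_consensus",
]

_SYMBOLS = "ACGTN-"
_CODE = {c: i for i, c in enumerate(_SYMBOLS)}
GAP_CODE = 5


@dataclass
class MultipleAlignment:
    """Equal-length gapped rows over {A,C,G,T,N,-}, in input member order."""

    rows: list[str]

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("alignment needs at least one row")
        width = len(self.rows[0])
        if any(len(r) != width for r in self.rows):
            raise ValueError("alignment rows differ in length")

    @property
    def width(self) -> int:
        return len(self.rows[0])

    def degapped(self, i: int) -> str:
        return self.rows[i].replace("-", "")

    def to_matrix(self) -> np.ndarray:
        return np.array(
            [[_CODE[c] for c in row] for row in self.rows], dtype=np.uint8
        )


@dataclass
class ConsensusRecord:
    name: str
    sequence: str
    cluster_id: int = 0

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty consensus sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)


def _encode(seq: str) -> np.ndarray:
    return np.array([_CODE.get(c, 4) for c in seq], dtype=np.uint8)


def _counts(matrix: np.ndarray) -> np.ndarray:
    """(L, 5) per-column counts of A,C,G,T,N (gaps excluded)."""
    L = matrix.shape[1]
    counts = np.zeros((L, 5), dtype=np.float64)
    for s in range(5):
        counts[:, s] = (matrix == s).sum(axis=0)
    return counts


def _kmer_distance_matrix(seqs: Sequence[str], k: int = 8) -> np.ndarray:
    """Condensed distance: 1 - shared k-mers / min(set sizes)."""
    sets = [{s[i : i + k] for i in range(max(0, len(s) - k + 1))} for s in seqs]
    n = len(seqs)
    out = []
    for i in range(n):
        for j in range(i + 1, n):
            denom = min(len(sets[i]), len(sets[j]))
            shared = len(sets[i] & sets[j]) if denom else 0
            out.append(1.0 - (shared / denom if denom else 0.0))
    return np.array(out)


def _merge(mat_a: np.ndarray, mat_b: np.ndarray) -> np.ndarray:
    ops = align_profiles(
        _counts(mat_a), mat_a.shape[0], _counts(mat_b), mat_b.shape[0]
    )
    ra, rb = mat_a.shape[0], mat_b.shape[0]
    out = np.full((ra + rb, len(ops)), GAP_CODE, dtype=np.uint8)
    ia = ib = 0
    for col, op in enumerate(ops):
        if op == 0:
            out[:ra, col] = mat_a[:, ia]
            out[ra:, col] = mat_b[:, ib]
            ia += 1
            ib += 1
        elif op == 1:
            out[:ra, col] = mat_a[:, ia]
            ia += 1
        else:
            out[ra:, col] = mat_b[:, ib]
            ib += 1
    return out


def progressive_msa(seqs: Sequence[str]) -> MultipleAlignment:
    """Guide-tree progressive alignment; deterministic for fixed input.

    A single sequence comes back as a one-row alignment.  De-gapping row i
    always reproduces member sequence i exactly.
    """
    if not seqs:
        raise ValueError("no sequences to align")
    if len(seqs) == 1:
        return MultipleAlignment([seqs[0]])
    if len(set(seqs)) == 1:
        return MultipleAlignment(list(seqs))
    profiles: dict[int, tuple[np.ndarray, list[int]]] = {
        i: (_encode(s)[None, :], [i]) for i, s in enumerate(seqs)
    }
    n = len(seqs)
    z = linkage(_kmer_distance_matrix(seqs), method="average")
    for t, (a, b, _, _) in enumerate(z):
        mat_a, idx_a = profiles.pop(int(a))
        mat_b, idx_b = profiles.pop(int(b))
        profiles[n + t] = (_merge(mat_a, mat_b), idx_a + idx_b)
    (matrix, order), = profiles.values()
    inv = np.argsort(order)
    rows = ["".join(_SYMBOLS[c] for c in matrix[i]) for i in inv]
    return MultipleAlignment(rows)


def majority_consensus(
    msa: MultipleAlignment, name: str = "consensus", cluster_id: int = 0
) -> ConsensusRecord:
    """Per-column majority base; gap-majority columns are omitted."""
    matrix = msa.to_matrix()
    nrows = matrix.shape[0]
    out: list[str] = []
    for col in range(matrix.shape[1]):
        counts = np.bincount(matrix[:, col], minlength=6)
        if counts[GAP_CODE] * 2 > nrows:
            continue
        base_counts = counts[:4]
        if base_counts.sum() == 0:
            out.append("N")
            continue
        out.append(_SYMBOLS[int(np.argmax(base_counts))])
    if not out:
        raise ValueError("consensus is empty (all columns gap-majority)")
    return ConsensusRecord(name, "".join(out), cluster_id=cluster_id)


def build_cluster_consensus(cluster: GapCluster) -> tuple[MultipleAlignment, ConsensusRecord]:
    """MSA + consensus of a cluster's member sequences; stores the consensus."""
    msa = progressive_msa([g.sequence for g in cluster.members])
    cons = majority_consensus(
        msa, name=f"GD_cluster_{cluster.cluster_id}", cluster_id=cluster.cluster_id
    )
    cluster.consensus = cons
    return msa, cons


def cluster_summary(cluster: GapCluster) -> tuple[int, float, float, int]:
    """(copy_number, mean_length, median_bias, consensus_length)."""
    if cluster.consensus is None:
        raise ValueError("cluster has no consensus yet")
    return (
        cluster.copy_number,
        cluster.mean_length,
        cluster.median_bias,
        cluster.consensus.length,
    )


def refine_consensus(
    cluster: GapCluster, contigs: ContigSet, flank: int = 3000
) -> ConsensusRecord:
    """Re-derive a cluster consensus from member loci extended by ``flank``.

    Useful when reads mis-mapped onto degraded older copies truncated the
    original coverage gaps: the flanking sequence lets the alignment extend
    beyond the gap boundaries, so element sequence shared by all members but
    lost from the gap calls re-enters the consensus.  Flank columns that are
    specific to one locus carry no consistent majority and either drop out
    as gap-majority columns or contribute low-confidence padding.
    """
    seqs = []
    for g in cluster.members:
        iv = g.interval
        start = max(0, iv.start - flank)
        end = min(contigs.length(iv.contig), iv.end + flank)
        seqs.append(contigs.slice(GenomicInterval(iv.contig, start, end)))
    msa = progressive_msa(seqs)
    cons = majority_consensus(
        msa, name=f"GD_cluster_{cluster.cluster_id}_refined",
        cluster_id=cluster.cluster_id,
    )
    return cons
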