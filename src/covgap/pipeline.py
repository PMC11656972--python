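"""Pipeline orchestration: map -> depth -> gaps -> cluster -> consensus -> report.

The fixed output contract of a run directory:

* ``GD-candidates.fasta``     one consensus per repetitive cluster
* ``GD-non-repetitive.fasta`` every gap sequence outside a cluster
* ``GD.bed``                  coordinates + bias of every retained gap
* ``GD-summary.tsv``          per-cluster copy number, lengths, median bias
* ``intermediates/``          gap FASTA, similarity hits, per-cluster MSAs, log

Empty results are a success (empty but present output files); a run in which
no read aligns at all is a hard error.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from . import clustering, consensus as consensus_mod, gaps as gaps_mod
from .io_formats import (
    ContigSet,
    DepthTrack,
    ReadRecord,
    depth_from_sam,
    read_depth_table,
    read_fasta,
    read_fastq,
    write_fasta,
    write_gap_bed,
)
from .gaps import CoverageGap, GapParams
from .clustering import GapCluster
from .mapping import depth_from_reads

__all__ = ["RunConfig", "RunResult", "run_pipeline", "summary_report"]

logger = logging.getLogger("covgap")

CANDIDATES_FASTA = "GD-candidates.fasta"
NON_REPETITIVE_FASTA = "GD-non-repetitive.fasta"
GAP_BED = "GD.bed"
SUMMARY_TSV = "GD-summary.tsv"


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``reads`` (FASTQ path or in-memory read list), ``sam``
    (alignment path) or ``depth`` (per-base depth table path / DepthTrack)
    must be provided.
    """

    assembly: Union[str, ContigSet]
    out_dir: Union[str, Path]
    reads: Union[str, Sequence[ReadRecord], None] = None
    sam: Optional[str] = None
    depth: Union[str, DepthTrack, None] = None
    gap_params: GapParams = field(default_factory=GapParams)
    min_identity: float = 80.0
    min_cov: float = 0.5
    min_cluster_members: int = 3
    mapper_k: int = 17
    max_edit_frac: float = 0.1
    seed: int = 0
    keep_intermediates: bool = True
    index: Optional[object] = None  # prebuilt SeedIndex over the assembly

    def __post_init__(self) -> None:
        n_inputs = sum(x is not None for x in (self.reads, self.sam, self.depth))
        if n_inputs != 1:
            raise ValueError("provide exactly one of reads / sam / depth")


@dataclass
class RunResult:
    clusters: list[GapCluster]
    non_repetitive: list[CoverageGap]
    gaps: list[CoverageGap]
    depth: DepthTrack
    paths: dict[str, str]
    stage_counts: dict[str, int]


def _compute_depth(config: RunConfig, assembly: ContigSet) -> tuple[DepthTrack, dict]:
    counts: dict[str, int] = {}
    if config.depth is not None:
        if isinstance(config.depth, DepthTrack):
            return config.depth, counts
        return read_depth_table(config.depth, assembly), counts
    if config.sam is not None:
        return depth_from_sam(config.sam, assembly), counts
    reads = config.reads
    if isinstance(reads, (str, Path)):
        reads = read_fastq(reads)
    track, stats, _ = depth_from_reads(
        reads,
        assembly,
        index=config.index,
        k=config.mapper_k,
        max_edit_frac=config.max_edit_frac,
    )
    counts.update(
        reads_total=stats.total,
        reads_mapped=stats.mapped,
        reads_unmapped=stats.unmapped,
        reads_fast_path=stats.fast_path,
    )
    return track, counts


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute the full workflow and write the four primary outputs."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    inter_dir = out_dir / "intermediates"
    if config.keep_intermediates:
        inter_dir.mkdir(exist_ok=True)

    assembly = (
        config.assembly
        if isinstance(config.assembly, ContigSet)
        else read_fasta(config.assembly)
    )
    track, counts = _compute_depth(config, assembly)
    if track.genome_mean == 0:
        raise RuntimeError("no reads aligned: genome-wide mean depth is zero")

    p = config.gap_params
    raw = gaps_mod.detect_gaps(track, p.depth_threshold)
    merged = gaps_mod.merge_gaps(raw, p.merge_distance)
    kept = gaps_mod.filter_by_length(merged, p.min_length)
    counts.update(
        gaps_raw=len(raw), gaps_merged=len(merged), gaps_retained=len(kept)
    )
    logger.info(
        "gaps: %d raw, %d after merge (d=%d), %d >= %d bp",
        len(raw), len(merged), p.merge_distance, len(kept), p.min_length,
    )

    gap_records = gaps_mod.extract_sequences(kept, assembly, track, flank=p.flank)
    paths = {
        "candidates": str(out_dir / CANDIDATES_FASTA),
        "non_repetitive": str(out_dir / NON_REPETITIVE_FASTA),
        "bed": str(out_dir / GAP_BED),
        "summary": str(out_dir / SUMMARY_TSV),
    }
    write_gap_bed(gap_records, paths["bed"])

    if not gap_records:
        logger.info("no coverage gaps retained; writing empty outputs")
        write_fasta([], paths["candidates"])
        write_fasta([], paths["non_repetitive"])
        _write_summary([], paths["summary"])
        return RunResult([], [], [], track, paths, counts)

    if config.keep_intermediates:
        write_fasta(
            [(g.name, g.sequence) for g in gap_records],
            inter_dir / "gaps.fasta",
        )

    edges = clustering.pairwise_hits(
        [g.sequence for g in gap_records],
        min_identity=config.min_identity,
        min_cov=config.min_cov,
    )
    groups = clustering.connected_components(edges, len(gap_records))
    clusters, non_repetitive = clustering.partition_repetitive(
        groups, gap_records, min_members=config.min_cluster_members
    )
    counts.update(similarity_edges=len(edges), clusters=len(clusters))
    if config.keep_intermediates:
        with open(inter_dir / "hits.tsv", "w") as fh:
            fh.write("query\tsubject\tidentity\taln_len\tcoverage\n")
            for e in edges:
                fh.write(
                    f"{e.query}\t{e.subject}\t{e.identity:.2f}\t"
                    f"{e.aln_len}\t{e.coverage:.3f}\n"
                )

    for cluster in clusters:
        msa, cons = consensus_mod.build_cluster_consensus(cluster)
        if config.keep_intermediates:
            write_fasta(
                [
                    (g.name, row)
                    for g, row in zip(cluster.members, msa.rows)
                ],
                inter_dir / f"cluster_{cluster.cluster_id}.msa.fasta",
            )

    write_fasta(
        [(c.consensus.name, c.consensus.sequence) for c in clusters],
        paths["candidates"],
    )
    write_fasta(
        [(g.name, g.sequence) for g in non_repetitive],
        paths["non_repetitive"],
    )
    _write_summary(clusters, paths["summary"])
    logger.info(
        "run complete: %d clusters, %d non-repetitive sequences",
        len(clusters), len(non_repetitive),
    )
    return RunResult(clusters, non_repetitive, gap_records, track, paths, counts)


def _summary_frame(clusters: Sequence[GapCluster]) -> pd.DataFrame:
    rows = [
        {
            "cluster": c.consensus.name if c.consensus else f"GD_cluster_{c.cluster_id}",
            "copy_number": c.copy_number,
            "mean_length": round(c.mean_length, 1),
            "consensus_length": c.consensus.length if c.consensus else 0,
            "median_bias": round(c.median_bias, 4),
        }
        for c in clusters
    ]
    df = pd.DataFrame(
        rows,
        columns=["cluster", "copy_number", "mean_length", "consensus_length", "median_bias"],
    )
    if len(df):
        df = df.sort_values(
            ["copy_number", "cluster"], ascending=[False, True]
        ).reset_index(drop=True)
    return df


def _write_summary(clusters: Sequence[GapCluster], path: str) -> None:
    _summary_frame(clusters).to_csv(path, sep="\t", index=False)


def summary_report(
    result: RunResult, plot_path: Optional[str] = None
) -> pd.DataFrame:
    """Cluster summary table (copy number descending); optional scatter plot.

    The plot shows consensus length vs copy number, colored by median bias;
    the returned table is identical whether or not a plot is written.
    """
    df = _summary_frame(result.clusters)
    if plot_path and len(df):
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4))
        sc = ax.scatter(
            df["consensus_length"],
            df["copy_number"],
            c=df["median_bias"],
            cmap="coolwarm",
            vmin=-1,
            vmax=1,
            s=40,
        )
        fig.colorbar(sc, ax=ax, label="median coverage bias")
        ax.set_xlabel("consensus length (bp)")
        ax.set_ylabel("copy number")
        fig.tight_layout()
        fig.savefig(plot_path, dpi=120)
        plt.close(fig)
    return df
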