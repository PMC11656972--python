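"""Synthetic validation data: TE-inserted genomes and short-read sets.

The generator reproduces the validation design used to benchmark the
method: a template genome (sample A), a modified genome carrying N identical
copies of a novel random sequence (sample P), and reads simulated from the
template in one of three modes:

* ``uniform`` — reads tile each contig at a fixed stride (deterministic);
* ``random`` — read starts drawn uniformly;
* ``ancient`` — short lognormal fragments (mean ~50 bp) with terminal
  cytosine deamination (C→T at the 5' end, G→A at the 3' end), mixed with
  10% bacterial contamination and 8% modern contamination, 82% endogenous.

The modern-contamination source defaults to the template itself (modern DNA
of the same organism does not carry the novel insertion); pass
``modern_genome`` to draw it from another genome, e.g. the modified one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .io_formats import ContigSet, GenomicInterval, ReadRecord, reverse_complement

__all__ = [
    "TruthSet",
    "AncientParams",
    "random_sequence",
    "insert_copies",
    "reads_uniform",
    "reads_random",
    "reads_ancient",
    "simulate_scenario",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class TruthSet:
    """Ground truth of a simulation: the insert and its loci on the modified genome."""

    insert_sequence: str
    loci: list[GenomicInterval]
    template: ContigSet

    def __post_init__(self) -> None:
        n = len(self.insert_sequence)
        for iv in self.loci:
            if len(iv) != n:
                raise ValueError(f"truth locus {iv.name} length != insert length {n}")
        ivs = sorted(self.loci, key=lambda i: (i.contig, i.start))
        for a, b in zip(ivs, ivs[1:]):
            if a.contig == b.contig and b.start < a.end:
                raise ValueError("truth loci overlap")


@dataclass
class AncientParams:
    """Ancient-DNA read model: fragmentation, deamination, contamination."""

    fragment_mean: float = 50.0
    fragment_sd: float = 15.0
    fragment_min: int = 25
    fragment_max: int = 150
    deamination_p0: float = 0.3
    deamination_decay: float = 0.5
    frac_bacterial: float = 0.10
    frac_modern: float = 0.08
    contaminant_length: int = 100_000

    def __post_init__(self) -> None:
        if self.frac_bacterial + self.frac_modern > 1:
            raise ValueError("contamination fractions exceed 1")

    @property
    def frac_endogenous(self) -> float:
        return 1.0 - self.frac_bacterial - self.frac_modern


def random_sequence(length: int, seed: int) -> str:
    """I.i.d. uniform A/C/G/T sequence, reproducible from the seed."""
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    return rng.choice(_BASES, size=length).tobytes().decode("ascii")


def insert_copies(
    template: ContigSet,
    insert: str,
    n: int,
    seed: int,
    min_separation: int = 25_000,
    end_margin: int = 10_000,
) -> tuple[ContigSet, TruthSet]:
    """Splice ``n`` copies of ``insert`` into the template at spaced points.

    Insertion points are drawn without replacement on the longest-first
    contigs, pairwise separated by at least ``min_separation`` and at least
    ``end_margin`` from contig ends, so that every bias flank is clean of
    neighboring insertions.  Truth loci are reported in modified-genome
    coordinates.  Removing the truth loci from the modified genome restores
    the template byte-for-byte.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    # greedily allocate insertions to the contig with the most remaining room
    usable = {
        name: max(0, template.length(name) - 2 * end_margin)
        for name in template
    }
    counts = {name: 0 for name in template}
    for _ in range(n):
        best = max(
            template.names,
            key=lambda nm: usable[nm] - counts[nm] * min_separation,
        )
        counts[best] += 1

    modified = ContigSet()
    loci: list[GenomicInterval] = []
    ins_len = len(insert)
    for name in template:
        seq = template[name]
        c = counts[name]
        if c == 0:
            modified.add(name, seq)
            continue
        span = template.length(name) - 2 * end_margin - (c - 1) * min_separation
        if span < c:
            raise ValueError(
                "template too short to place insertions at the required spacing"
            )
        picks = np.sort(rng.choice(span, size=c, replace=False))
        points = picks + end_margin + np.arange(c) * min_separation
        parts = []
        prev = 0
        for i, p in enumerate(points):
            p = int(p)
            parts.append(seq[prev:p])
            parts.append(insert)
            start = p + i * ins_len
            loci.append(GenomicInterval(name, start, start + ins_len))
            prev = p
        parts.append(seq[prev:])
        modified.add(name, "".join(parts))
    truth = TruthSet(insert, loci, template)
    return modified, truth


def _apply_substitutions(
    reads: list[ReadRecord], error_rate: float, rng: np.random.Generator
) -> list[ReadRecord]:
    if error_rate <= 0:
        return reads
    out = []
    alphabet = "ACGT"
    for r in reads:
        arr = list(r.sequence)
        hits = np.flatnonzero(rng.random(len(arr)) < error_rate)
        for i in hits:
            cur = arr[i]
            choices = [b for b in alphabet if b != cur]
            arr[i] = choices[int(rng.integers(3))]
        out.append(ReadRecord(r.id, "".join(arr)))
    return out


def reads_uniform(
    genome: ContigSet,
    coverage: float,
    read_length: int = 100,
    error_rate: float = 0.0,
    seed: int = 0,
) -> list[ReadRecord]:
    """Tile each contig at stride read_length / coverage (rounded).

    With error_rate = 0 the read set is fully deterministic and every read
    is an exact substring of the genome.
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    stride = max(1, round(read_length / coverage))
    reads: list[ReadRecord] = []
    for name in genome:
        seq = genome[name]
        for j, start in enumerate(range(0, len(seq) - read_length + 1, stride)):
            reads.append(
                ReadRecord(f"u_{name}_{j}", seq[start : start + read_length])
            )
    rng = np.random.default_rng(seed)
    return _apply_substitutions(reads, error_rate, rng)


def reads_random(
    genome: ContigSet,
    coverage: float,
    read_length: int = 100,
    error_rate: float = 0.0,
    seed: int = 0,
) -> list[ReadRecord]:
    """Uniformly placed reads, N = round(coverage * genome_length / read_length)."""
    rng = np.random.default_rng(seed)
    total = genome.total_length()
    n_reads = int(round(coverage * total / read_length))
    reads: list[ReadRecord] = []
    names = genome.names
    lengths = np.array([genome.length(n) for n in names], dtype=np.float64)
    alloc = np.floor(n_reads * lengths / lengths.sum()).astype(int)
    alloc[0] += n_reads - alloc.sum()
    for name, count in zip(names, alloc):
        seq = genome[name]
        hi = max(1, len(seq) - read_length + 1)
        starts = rng.integers(0, hi, size=count)
        for j, s in enumerate(starts):
            reads.append(ReadRecord(f"r_{name}_{j}", seq[s : s + read_length]))
    return _apply_substitutions(reads, error_rate, rng)


def _deaminate(seq: str, p0: float, decay: float, rng: np.random.Generator) -> str:
    if p0 <= 0:
        return seq
    arr = list(seq)
    L = len(arr)
    p = p0
    for i in range(L):
        if p < 1e-6:
            break
        if arr[i] == "C" and rng.random() < p:
            arr[i] = "T"
        p *= decay
    p = p0
    for i in range(L - 1, -1, -1):
        if p < 1e-6:
            break
        if arr[i] == "G" and rng.random() < p:
            arr[i] = "A"
        p *= decay
    return "".join(arr)


def _draw_fragments(
    genome: ContigSet,
    n: int,
    params: AncientParams,
    rng: np.random.Generator,
    prefix: str,
    damage: bool,
    read_length: Optional[int] = None,
) -> list[ReadRecord]:
    names = genome.names
    lengths = np.array([genome.length(nm) for nm in names], dtype=np.float64)
    probs = lengths / lengths.sum()
    which = rng.choice(len(names), size=n, p=probs)
    if read_length is None:
        sigma = np.sqrt(np.log1p((params.fragment_sd / params.fragment_mean) ** 2))
        mu = np.log(params.fragment_mean) - sigma**2 / 2
        frag = np.clip(
            np.round(rng.lognormal(mu, sigma, size=n)),
            params.fragment_min,
            params.fragment_max,
        ).astype(int)
    else:
        frag = np.full(n, read_length, dtype=int)
    reads = []
    for j in range(n):
        name = names[which[j]]
        seq = genome[name]
        fl = min(int(frag[j]), len(seq))
        start = int(rng.integers(0, len(seq) - fl + 1))
        s = seq[start : start + fl]
        if damage:
            s = _deaminate(s, params.deamination_p0, params.deamination_decay, rng)
        if rng.random() < 0.5:
            s = reverse_complement(s)
        reads.append(ReadRecord(f"{prefix}_{j}", s))
    return reads


def reads_ancient(
    genome: ContigSet,
    coverage: float,
    params: AncientParams | None = None,
    seed: int = 0,
    modern_genome: ContigSet | None = None,
) -> list[ReadRecord]:
    """Ancient-DNA-style read set from the (endogenous) template genome.

    Endogenous reads are damaged lognormal fragments of ``genome``;
    bacterial reads come from an independent seeded random contaminant
    sequence; modern-contamination reads are undamaged fixed-length reads
    from ``modern_genome`` (default: the template genome itself).  The
    requested ``coverage`` is the endogenous coverage of ``genome``.
    """
    params = params or AncientParams()
    rng = np.random.default_rng(seed)
    n_endo = int(round(coverage * genome.total_length() / params.fragment_mean))
    n_total = int(round(n_endo / params.frac_endogenous))
    cats = rng.choice(
        3,
        size=n_total,
        p=[params.frac_endogenous, params.frac_bacterial, params.frac_modern],
    )
    n_e = int((cats == 0).sum())
    n_b = int((cats == 1).sum())
    n_m = int((cats == 2).sum())
    contaminant = ContigSet(
        [("contaminant", random_sequence(params.contaminant_length, seed + 7919))]
    )
    modern = modern_genome if modern_genome is not None else genome
    reads = _draw_fragments(genome, n_e, params, rng, "endo", damage=True)
    reads += _draw_fragments(contaminant, n_b, params, rng, "bact", damage=True)
    reads += _draw_fragments(modern, n_m, params, rng, "modern", damage=False,
                             read_length=100)
    return reads


@dataclass
class Scenario:
    template: ContigSet
    modified: ContigSet
    truth: TruthSet
    reads: list[ReadRecord]


def simulate_scenario(
    mode: str = "uniform",
    coverage: float = 5.0,
    seed: int = 1,
    template_length: int = 2_000_000,
    n_copies: int = 25,
    insert_length: int = 5000,
    read_length: int = 100,
    error_rate: float = 0.0,
    template: ContigSet | None = None,
    ancient_params: AncientParams | None = None,
    read_seed: int | None = None,
) -> Scenario:
    """One full validation scenario from a single seed.

    The template defaults to a seeded random sequence of ``template_length``;
    the reads are always simulated from the template (sample A) and are meant
    to be mapped against the modified genome (sample P).  ``read_seed``
    decouples read placement from genome construction when given.
    """
    if template is None:
        template = ContigSet([("template", random_sequence(template_length, seed))])
    insert = random_sequence(insert_length, seed + 104729)
    modified, truth = insert_copies(template, insert, n_copies, seed + 224737)
    rseed = seed + 350377 if read_seed is None else read_seed
    if mode == "uniform":
        reads = reads_uniform(template, coverage, read_length, error_rate, seed=rseed)
    elif mode == "random":
        reads = reads_random(template, coverage, read_length, error_rate, seed=rseed)
    elif mode == "ancient":
        reads = reads_ancient(
            template, coverage, ancient_params, seed=rseed
        )
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return Scenario(template, modified, truth, reads)
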