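# covgap

`covgap` finds genomic sequences that are **present in one sample's assembly
(P) but absent from another sample's short reads (A)** — the set P − A.
The motivating application is the detection of recent transposable-element
(TE) invasions: a TE family that spread through a population after sample A
was collected leaves insertions in the assembly of a recent sample P, and
when the reads of A are aligned to P every such insertion appears as a
**coverage gap**. The method needs no repeat library, which makes it suited
to museum specimens, non-model organisms, and newly invading elements.

## Method

1. **Align** the reads of A to the assembly of P with a local aligner
   (built-in seed-and-extend mapper, or bring your own SAM). Local
   alignment matters: read ends continuing into sequence absent from A are
   soft-clipped, so per-base depth stops exactly at each insertion junction.
2. **Call gaps**: maximal runs of positions with depth ≤ t (default t = 0,
   i.e. zero coverage), merge gaps separated by ≤ d bases (default 100) to
   tolerate spurious read placements, and keep gaps ≥ 1000 bp.
3. **Score** each gap with the coverage bias

   bias = 2·f / (g + f) − 1

   where *f* is the mean depth in the 10-kb windows flanking the gap and
   *g* the genome-wide mean depth. bias ≈ 0 marks trustworthy candidates
   (flanks look like the genomic average); values near ±1 flag artifacts
   such as telomeric regions where little of A maps at all.
4. **Cluster** the extracted gap sequences by pairwise similarity
   (≥ 80% identity over ≥ 50% of the shorter sequence, both strands,
   single linkage). Clusters with ≥ 3 members are reported as repetitive
   candidates — the dispersed insertions of one family — everything else as
   non-repetitive.
5. **Consensus**: each cluster gets a progressive multiple sequence
   alignment and a simple majority-rule consensus (gap-majority columns are
   dropped). The cluster's bias is the median of its members' biases.

Outputs of a run directory: `GD-candidates.fasta` (one consensus per
cluster), `GD-non-repetitive.fasta`, `GD.bed` (coordinates + bias of every
retained gap), `GD-summary.tsv` (copy number, mean member length, consensus
length, median bias per cluster), plus intermediates.

The package also ships the simulation harness used to validate the method
(TE-inserted genomes; uniform, random and ancient-DNA read models with
fragmentation, terminal deamination and contamination) and the evaluation
code that scores a run against the simulated truth (TP, FP, consensus
length and identity).

## Worked example

Simulate a benchmark (25 copies of a 5000-bp random insert in a 2-Mb
genome; error-free uniform 5× reads from the insert-free template), run the
pipeline, and score it:

```bash
covgap simulate --mode uniform --coverage 5 --seed 1 --out sim/
covgap run --assembly sim/modified.fasta --reads sim/reads.fastq --out run/
covgap evaluate --run-dir run/ --truth-bed sim/truth.bed \
    --insert-fasta sim/insert.fasta --assembly sim/modified.fasta
```

The `run` step prints the cluster summary table:

```
     cluster  copy_number  mean_length  consensus_length  median_bias
GD_cluster_1           25       4999.5              5000       0.0505
```

one repetitive cluster of 25 members (the 25 insertions), whose 5000-bp
consensus is the reconstructed element; the median bias near 0 marks it as
a reliable candidate. The `evaluate` step prints

```
{"TP": 25, "FP_nr": 0, "FP_r": 0, "len_bp": 5000, "sim_pct": 100.0}
```

all 25 insertions recovered, no false positives, and the consensus is 100%
identical to the simulated element.

The same machinery is available as a library:

```python
from covgap import RunConfig, run_pipeline, simulate_scenario, metrics_row

sc = simulate_scenario(mode="ancient", coverage=5, seed=1)
result = run_pipeline(RunConfig(assembly=sc.modified, out_dir="run", reads=sc.reads))
print(metrics_row(result.clusters, result.non_repetitive, sc.truth))
```

## Notes

- `docs/methods.md` describes the model, parameter defaults, simulation
  design and numerical choices in detail.
- Not a CNV caller: the method detects presence/absence, not copy-number
  differences between samples that share the sequence.
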