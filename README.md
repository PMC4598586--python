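# mrrbs

Simulation and analysis toolkit for **double-digest reduced-representation
bisulfite sequencing (mRRBS)** — the protocol that concentrates bisulfite
sequencing on a reproducible ~1–2% subset of a plant genome by cutting with
two restriction enzymes (SacI `GAGCTC` and MseI `TTAA`), gel-selecting
250–500 bp fragments, and sequencing paired 100-bp reads from the fragment
ends.

The package is aimed at methods work on polyploid plant methylomes: it lets
you generate a synthetic genome with a known ("truth") methylome, push reads
through the same analysis a real experiment would use, and check how well
every downstream quantity is recovered. The analysis layer is independent of
the simulator and applies to any data in the supported formats.

## What it implements

* **Synthetic data** (`mrrbs.simulate`) — multi-chromosome genomes with
  gene models (exon/intron), TE-dense pericentromeric blocks and
  tandem/inverted repeat tracks; per-cytosine truth methylomes with
  context- and component-dependent levels (CG ≥ CHG ≥ CHH; TE > intron >
  exon); sample-vs-reference SNPs; non-directional PE100 bisulfite reads
  with per-molecule methylation, configurable conversion efficiency and
  error rate; parallel non-bisulfite (ddRAD) reads; RPKM tables negatively
  coupled to genic methylation with subgenome (LF/MF1/MF2) and copy-number
  (1/2/3) effects.
* **In-silico digestion** (`mrrbs.digest`) — double digestion, inclusive
  250–500 bp size selection, the mixed-end adaptor rule, and capture
  statistics per cytosine context.
* **Preprocessing** (`mrrbs.preprocess`) — 5′ enzyme-residue trimming
  (including bisulfite-converted residue forms), retention of the first
  75 bp, and the pair-level >5 %-of-bases-under-Q30 filter.
* **Alignment** (`mrrbs.bsalign`) — non-directional three-letter bisulfite
  alignment under all four strand hypotheses (OT/OB/CTOT/CTOB) with an
  exact k-mer seed, full verification at ≤1 mismatch per pair in converted
  space, and a strict unique-best filter; a two-hypothesis plain mode for
  ddRAD reads.
* **Calling** (`mrrbs.methcall`) — reference-based CG/CHG/CHH
  classification, mate-overlap-deduplicated pileup at base quality ≥ 20,
  level calls at depth ≥ 10, permissive SNP calling (≥1 high-quality
  non-reference base), and masking of methylation sites whose context
  motif overlaps a candidate SNP.
* **Profiles** (`mrrbs.profiles`) — 200-kb/100-kb sliding windows with
  repeat content, strand-aware component means (1-kb flanks, 200-bp
  promoters, exons, introns, TE bodies), 10-decile metagene profiles with
  1-kb flanks, and methylation-level histograms.
* **Stratification** (`mrrbs.stratify`) — pooled methylation by subgenome
  or copy class, pairwise 1-df chi-square tests against the 6.63 (P < 0.01)
  criterion, RPKM classes (low ≤ 5 < medium ≤ 50 < high), class-distribution
  tests with compact significance letters, and the methylation–expression
  association summary.
* **Orchestration** (`mrrbs.pipeline`, `mrrbs.cli`) — a single-seed
  deterministic pipeline with per-stage counters, plus a thin `mrrbs`
  command-line interface (`simulate`, `digest`, `preprocess`, `align`,
  `call`, `mask`, `profile`, `stratify`, `run`).

## Worked example

```python
from mrrbs.pipeline import PipelineConfig, run_pipeline

result = run_pipeline(PipelineConfig(seed=1), outdir="run1")
print(result.components.query("context == 'CG'")
      [["component", "n_sites", "read_level"]])
```

```
     component  n_sites  read_level
0     upstream      261    0.365643
3     promoter       44    0.269714
6         exon      286    0.255127
9       intron      349    0.554161
12  downstream      191    0.415734
15          te      366    0.885678
```

The default configuration simulates a 2.4-Mb genome whose ground-truth CG
means are 0.880 in TE bodies, 0.544 in introns and 0.251 in exons; the
pooled CG level of the called sites (depth ≥ 10, SNP-masked) recovers each
component mean within sampling error. `run1/` holds every intermediate in
its standard format (FASTA, GFF3, BED, gzip FASTQ, SAM, VCF, TSV,
bedGraph) plus `report.json`/`report.md` with per-stage counts.

The `examples/` directory contains one short narrative script per
capability (digestion and capture, read simulation and alignment, calling
and masking, profiles, subgenome/expression stratification).

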