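# Methods

This note records the models, defaults and numerical choices behind the
toolkit, and what the synthetic studies do and do not demonstrate.

## The reduced representation

A double digest with SacI (`GAGCT^C`, cut offset 5) and MseI (`T^TAA`,
offset 1) fragments the genome at the merged cut list; fragments tile each
chromosome exactly. Sticky-end overhangs (≤4 bp) are ignored for length
accounting because fragment sizing happens on a gel. Size selection keeps
250–500 bp inclusive on both ends. Because the two adaptors are
enzyme-specific, only fragments with one SacI and one MseI boundary
amplify; this mixed-end rule is on by default and configurable off for
sensitivity analysis. Chromosome-end fragments never satisfy it. The
capture window of a retained fragment is the first 75 bases inward from
each end — the post-trim read span, not the raw 100 bp — clipped at the
fragment middle so short fragments are counted once. Whether the original
in-silico analysis required mixed ends or counted whole fragments is not
recoverable; both switches are exposed.

## The synthetic genome

Defaults describe the standard study genome: four 600-kb chromosomes
(~2.4 Mb) at 45% GC (rice-like), 260 genes, 380 TEs with 70% in a central
block covering the middle 30% of each chromosome (a pericentromere proxy),
and 70 tandem/inverted repeat tracks whose sequence is actually written
into the genome. Genes live in the chromosome arms with a 2.4-kb reserved
gap so 1-kb flanks never collide; exon counts are 1 + Poisson(3), exon
lengths lognormal (median 250 bp), intron lengths uniform 100–600 bp.
Subgenome labels are drawn LF/MF1/MF2 at 0.46/0.30/0.24 (the retention
hierarchy of a fractionated mesohexaploid) and copy classes 1/2/3 at
0.40/0.35/0.25. Feature placement distributes slack between items
multinomially, so packing succeeds whenever the features fit and the
layout stays uniform-ish; infeasible requests raise a `PackingError`.

At 45% GC an i.i.d. background yields a mixed-end 250–500 bp capture of
roughly 1% of all cytosine sites (~2,400 captured CG sites at 2.4 Mb). A
real genome's site clustering gives somewhat higher capture; the synthetic
figure is the desk-scale analogue and is reported per run by
`capture_stats`.

## The truth methylome

Every cytosine on both strands receives one true level. Component
priority for overlapping features is TE > exon > intron > promoter >
flank > intergenic (TEs dominate the methylation signal). Default
component means:

| component  | CG    | CHG   | CHH   |
|------------|-------|-------|-------|
| TE body    | 0.880 | 0.540 | 0.177 |
| intron     | 0.544 | 0.220 | 0.059 |
| exon       | 0.251 | 0.088 | 0.027 |
| promoter   | 0.250 | 0.090 | 0.030 |
| flank 1 kb | 0.400 | 0.150 | 0.050 |
| intergenic | 0.650 | 0.400 | 0.100 |

Two distribution families are available per component × context: a
two-point {0,1} mixture (weight = the mean) and a Beta with concentration
ν = 50. The default is Beta: for component-mean recovery the estimand is
the component mean, and a two-point family would make the captured
subset's own truth mean fluctuate by >2 percentage points at desk scale —
sinking even a perfect estimator. The two-point family is what real CG
sites look like (bimodal), and the genome-wide mixture preset
(`MethylationModel.genome_two_point`, P(CG)=0.524, P(CHG)=0.318,
P(CHH)=0.083) uses it throughout. Subgenome/copy offsets shift the genic
components of labelled genes and are zero by default.

## Read simulation

Reads are non-directional PE100 from fragment ends inward. Methylation is
drawn once per cytosine per sampled molecule (molecules carry one
epiallele; mates stay consistent); unmethylated cytosines convert to T
with efficiency 0.995 (a two-treatment protocol publishes no number; this
is declared, not inferred). The four bisulfite strands OT/OB/CTOT/CTOB
are equiprobable. `coverage_target` (default 20) is the expected
*informative* coverage per cytosine site; since one molecule reports one
strand, the simulator draws Poisson(2 × target) pairs per fragment.
Sequencing errors are uniform substitutions at rate 1e-3; qualities are
Normal(38, 3) truncated to [2, 40] with a 2% "degraded" mate fraction at
mean Q25 (these feed the quality filter; errors and qualities are
independent, a simplification). Fragments under 30 bp are skipped and
counted. Read names carry `chrom:start:end:strand:bs-strand:serial` so
oracle tests can score alignment without auxiliary files. ddRAD reads use
the same machinery without conversion.

## Preprocessing

The 5′ residual ligation scars are the reverse-strand enzyme residues
AGCTC (SacI) and TAA (MseI); their bisulfite images are deterministic
(each C may read T, or each G may read A), and all variants are stripped
at 0 mismatches. Stripping applies only to reads longer than the 75-bp
retention length — raw reads — which makes trimming exactly idempotent
and prevents misfiring on genomic sequence that begins with a
residue-like 5-mer. The quality rule discards a pair when either mate has
strictly more than 5% of bases under Q30 (a boundary read at exactly 5%
is kept); the discard is pair-level because alignment is paired. Whether
the original filter acted per mate or per pair is unstated; per-mate
trigger with pair-level discard is the choice here.

## Alignment

The multi-seed aligner of the reference tools is simplified to exact
k-mer seeds (k = 20) plus full verification of both mates with a total
substitution budget of 1 per pair, counted in converted space so retained
methylated cytosines are never charged. All four strand hypotheses are
two converted alphabets × two orientations; candidates must have proper
orientation and a mate span ≤ 520 bp (size-selected fragments cannot
exceed 500 bp; the margin absorbs residue trimming). A pair is reported
only when exactly one location attains the best score; ties are discarded
as ambiguous, mirroring a uniquely-mapped filter. Seeding from the left
mate alone is complete whenever that mate holds max_mm + 1 disjoint
seeds (a within-budget candidate always keeps one exact seed); the
mirrored pass runs only for shorter mates. No indels: the simulator emits
none and the retention contract allows substitutions only. Exhaustive
all-position scoring is the test oracle for this whole section.

## Calling and masking

Context is classified from the reference only (never from converted
reads): C followed by G → CG, else next-next G → CHG, else CHH; sites
whose context is undefined at a chromosome edge or flanking N are
excluded. Pileup takes read 1's base where mates overlap (one molecule,
one observation), skips bases under Q20, and emits calls at depth ≥ 10.
CG sites stay per-strand (no symmetric merging), matching per-cytosine
reporting. SNP calling from the ddRAD alignments is deliberately
permissive — one high-quality non-reference base suffices — because
candidates are only used to *remove* methylation sites; false positives
cost sites, never bias. Masking removes a call when any candidate SNP
falls in the strand-oriented motif window (C..C+1 for CG, C..C+2 for
CHG/CHH); whether the original exclusion used the C position only or the
whole motif is unstated, so the window rule is the default and the C-only
variant is a parameter away.

With conversion efficiency e < 1 the expected level bias at a truly
unmethylated site is (1 − e) ≈ 0.005; at 20× informative depth this is
negligible against binomial noise, and the simulation tests verify it.

## Profiles and stratification

Window profiles use 200-kb windows advancing by 100 kb, partial tail
windows included; means are unweighted over called sites. Component means
pool sites (each called site weighted equally) rather than averaging
per-gene means — the source convention is unknown, pooling is the
variance-stable default, and read-pooled totals are carried alongside.
Metagene bodies split into 10 equal bins (remainder bases to the last
bin) with 100-bp flank bins over 1-kb flanks; minus-strand features are
mirrored so bin 1 is 5′. Histograms use an exact-zero bin plus ten
(0–10]…(90–100] bins.

Stratified chi-square tests run on pooled read counts (levels derive from
reads; a site-count mode would be a config switch away), 1 df, no
continuity correction, significant above 6.63 (the 0.99 quantile of the
1-df null). No multiple-testing correction is applied — the criterion is
a fixed per-comparison threshold, noted here deliberately. Compact
letters group strata greedily by non-significant pairs, ordered by
descending high-expression fraction with name tie-breaks.

## Expression model

log2(RPKM) = base + subgenome effect + copy effect + coupling × (gene CG
methylation − 0.3) + Normal(0, dispersion), with defaults base 2.0,
effects LF +0.8 / MF1 −0.5 / MF2 0.0 and copy 1 −0.8 / 2 +0.2 / 3 +0.6
(transcription hierarchy LF > MF2 > MF1 and multi-copy > single-copy),
dispersion 2.2 and coupling −3.

## Validation studies and their scale

The acceptance studies were sized by a-priori power analysis:

* **Component recovery** uses the default 2.4-Mb genome, 20× site
  coverage, conversion 0.995, error 1e-3. With Beta(ν=50) truth the
  captured per-component CG site counts (≈300–400) put the sampling SE of
  each recovered mean at 0.4–0.9 points against a ±2-point check.
* **Genome-wide mixture** uses a 6-Mb genome: a two-point site mixture
  has per-site SD 0.5, so ~6,000 captured CG sites are needed to hold the
  SE near 0.65 points against a ±1.5-point check.
* **Injected-effect power**: 2-point subgenome offsets with 30,000 pooled
  reads per stratum put the adjacent-pair noncentral z near 5, so all
  three pairwise 1-df tests clear 6.63 in ≳99% of replicates.
* **Methylation–expression association** runs on depth-20 calls sampled
  from the truth methylome over *all* genic CG sites. The reduced
  representation covers only ~16% of genes with one or two windows each,
  and a gene's captured-window mean correlates with its whole-gene mean
  (the quantity expression couples to) at only r ≈ 0.34 — so sparse-call
  class means are dominated by capture sampling, which is a property of
  RRBS itself, not of the association analysis under test. The replicate
  model uses strong coupling (−15, dispersion 0.3) so the class split is
  methylation-driven.

What passing these studies shows: digestion, selection, trimming,
filtering, four-strand alignment, overlap-deduplicated pileup,
depth-filtered calling, SNP masking and the stratified statistics are
mutually consistent and recover known truth at desk scale. What they do
not show: behaviour on real libraries with adapter chimeras, M-bias,
PCR duplicates, indels, methylation-sensitive enzyme effects,
context-dependent conversion failure or genuine repeat families — none of
which the generator emulates.

## Determinism

Every stage's randomness flows from one configured seed through spawned
child seed sequences; reruns are byte-identical, and results do not
depend on thread count (the implementation is single-threaded).
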