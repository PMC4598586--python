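"""End-to-end orchestration: simulate -> digest -> preprocess -> align ->
call -> mask -> profiles -> stratify.

Every stage's record counts and filter losses are collected into a
:class:`RunReport`; all randomness flows from the single configured seed
through spawned child seeds, so a rerun with the same configuration is
byte-identical. ``truth_mode`` places reads by their simulated provenance
instead of searching, which serves as a pipeline self-oracle under zero
sequencing error.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .bsalign import (_CONVERTERS, AlignmentRecord, _mismatches_at, _orient_pair,
                      align_reads, build_bs_index)
from .digest import DigestParams, capture_stats, double_digest, select_representation
from .genome import AnnotationSet, ReferenceSet
from .methcall import (call_levels, call_snps, classify_cytosines, mask_sites,
                       pileup)
from .preprocess import preprocess_pairs
from .profiles import (component_means, level_histogram, metagene_profile,
                       window_profile)
from .simulate import (ExpressionModel, GenomeSpec, MethylationModel,
                       apply_variants, generate_expression, generate_genome,
                       generate_methylome, simulate_ddrad_reads,
                       simulate_rrbs_reads, ReadSimParams)
from .stratify import (bin_expression, expression_crosstab,
                       methylation_expression_association, stratum_means,
                       stratum_pairwise_tests)


@dataclass
class PipelineConfig:
    """All tunables of a synthetic end-to-end run, with standard defaults.

    Defaults: 75-bp retention, >5% of bases under Q30 discards a pair, one
    mismatch per pair, Q>=20 bases, depth >=10 calls, 250-500 bp size
    selection, 200-kb/100-kb windows, 1-kb flanks, 200-bp promoters, 10
    body bins, RPKM classes at 5/50 and the 1-df P=0.01 criterion.
    """

    seed: int = 0
    genome: GenomeSpec = field(default_factory=GenomeSpec)
    methylation_model: str = "component"  # or "genome_two_point"
    subgenome_offsets: dict = field(default_factory=dict)
    copy_offsets: dict = field(default_factory=dict)
    p_cg: float = 0.524
    p_chg: float = 0.318
    p_chh: float = 0.083
    snp_rate: float = 0.001
    digest: DigestParams = field(default_factory=DigestParams)
    readsim: ReadSimParams = field(default_factory=ReadSimParams)
    ddrad_coverage: float = 20.0
    expression: ExpressionModel = field(default_factory=ExpressionModel)
    keep_len: int = 75
    max_low_frac: float = 0.05
    min_q: int = 30
    index_k: int = 20
    max_mm: int = 1
    max_span: int = 520
    min_baseq: int = 20
    min_depth: int = 10
    win: int = 200_000
    step: int = 100_000
    flank: int = 1000
    promoter: int = 200
    body_bins: int = 10
    flank_bin: int = 100
    rpkm_low: float = 5.0
    rpkm_high: float = 50.0
    chi2_alpha: float = 0.01
    truth_mode: bool = False

    def __post_init__(self) -> None:
        if self.keep_len <= 0 or self.min_depth <= 0 or self.index_k < 10:
            raise ValueError("invalid preprocessing/calling parameters")
        if not 0 <= self.max_low_frac <= 1:
            raise ValueError("max_low_frac must lie in [0,1]")
        if self.win < self.step:
            raise ValueError("window must be >= step")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = dict(raw)
        if "genome" in kwargs:
            kwargs["genome"] = GenomeSpec(**kwargs["genome"])
        if "digest" in kwargs:
            kwargs["digest"] = DigestParams(**kwargs["digest"])
        if "readsim" in kwargs:
            kwargs["readsim"] = ReadSimParams(**kwargs["readsim"])
        if "expression" in kwargs:
            kwargs["expression"] = ExpressionModel(**kwargs["expression"])
        return cls(**kwargs)


@dataclass
class RunReport:
    stages: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)

    def record(self, stage: str, **counters) -> None:
        self.stages[stage] = {k: (int(v) if isinstance(v, (int, np.integer)) else v)
                              for k, v in counters.items()}

    def to_json(self) -> str:
        return json.dumps({"stages": self.stages, "outputs": self.outputs},
                          indent=2, default=str)


@dataclass
class PipelineResult:
    """In-memory artifacts of a run (tables also land on disk when an
    output directory is given)."""

    config: PipelineConfig
    report: RunReport
    ref: ReferenceSet
    ann: AnnotationSet
    truth: object
    sample_ref: ReferenceSet
    variants_true: pd.DataFrame
    fragments: list
    selected: list
    capture: pd.DataFrame
    calls: pd.DataFrame
    masked_calls: pd.DataFrame
    snps: pd.DataFrame
    windows: pd.DataFrame
    components: pd.DataFrame
    metagene_genes: pd.DataFrame
    metagene_tes: pd.DataFrame
    histogram: pd.DataFrame
    extremes: pd.DataFrame
    expression: pd.DataFrame
    classes: pd.DataFrame
    subgenome_summary: pd.DataFrame
    copy_summary: pd.DataFrame
    subgenome_tests: pd.DataFrame
    copy_tests: pd.DataFrame
    subgenome_crosstab: pd.DataFrame
    copy_crosstab: pd.DataFrame
    association: object


def component_recovery_config(seed: int = 0) -> PipelineConfig:
    """Standard component-mean recovery study: ~2.4 Mb genome, component
    ground-truth CG means (TE 0.880 / intron 0.544 / exon 0.251), 20x site
    coverage, conversion efficiency 0.995, error 0.001."""
    return PipelineConfig(seed=seed)


def genome_mixture_config(seed: int = 0) -> PipelineConfig:
    """Genome-wide two-point mixture study: per-site {0,1} CG truth with
    P(methylated) = 0.524. Uses a 6 Mb genome so the captured CG site count
    holds the sampling SE of the site-mixture mean near 0.65 points."""
    return PipelineConfig(
        seed=seed,
        genome=GenomeSpec(n_chromosomes=4, chrom_length=1_500_000,
                          n_genes=650, n_tes=950),
        methylation_model="genome_two_point",
    )


_BS_MAP = {"OT": ("CT", "+"), "CTOT": ("CT", "-"),
           "OB": ("GA", "-"), "CTOB": ("GA", "+")}


def place_by_provenance(pairs, index, max_trim: int = 6) -> list[AlignmentRecord]:
    """Oracle placement: reconstruct each pair's alignment from the
    provenance encoded in its read name (no search, no uniqueness filter)."""
    records = []
    for pair in pairs:
        chrom, start, end, src, bs, _ = pair.name.split(":")
        start, end = int(start), int(end)
        conv, r1s = ("raw", src) if bs == "NA" else _BS_MAP[bs]
        o1, o2, s1, q1, s2, q2 = _orient_pair(pair, r1s)
        convert = _CONVERTERS[conv]
        garr = index.genomes[conv][chrom]
        left, right = (o1, o2) if r1s == "+" else (o2, o1)
        cl, cr = convert(left), convert(right)

        def best_offset(read, anchor_left: bool):
            best = None
            for t in range(max_trim):
                p = start + t if anchor_left else end - t - len(read)
                mm = _mismatches_at(garr, p, read)
                if mm is not None and (best is None or mm < best[1]):
                    best = (p, mm)
            return best

        bl = best_offset(cl, True)
        br = best_offset(cr, False)
        if bl is None or br is None:
            continue
        (pl, mml), (pr, mmr) = bl, br
        pos1, pos2 = (pl, pr) if r1s == "+" else (pr, pl)
        records.append(AlignmentRecord(
            name=pair.name, chrom=chrom, pos1=pos1, pos2=pos2, r1_strand=r1s,
            bs_strand=bs, conversion=conv, mismatches=mml + mmr,
            seq1_oriented=s1, qual1_oriented=q1,
            seq2_oriented=s2, qual2_oriented=q2))
    return records


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None,
                 ) -> PipelineResult:
    """Execute the full synthetic pipeline; see module docstring.

    Any stage failure is re-raised as :class:`PipelineStageError` naming
    the stage; partial in-memory results are discarded.
    """
    _CURRENT_STAGE[0] = "configure"
    try:
        return _run_pipeline(config, outdir)
    except Exception as e:
        raise PipelineStageError(_CURRENT_STAGE[0], e) from e


_CURRENT_STAGE = ["configure"]


def _stage(name: str) -> None:
    _CURRENT_STAGE[0] = name


def _run_pipeline(config: PipelineConfig, outdir: str | Path | None,
                  ) -> PipelineResult:
    report = RunReport()
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(6)]

    _stage("simulate_genome")
    ref, ann = generate_genome(replace(config.genome, seed=seeds[0]))
    report.record("genome", chromosomes=len(ref.names()),
                  total_bp=ref.total_length, genes=len(ann.genes),
                  tes=len(ann.tes), repeats=len(ann.repeats))

    if config.methylation_model == "component":
        model = MethylationModel.component_default(
            subgenome_offsets=dict(config.subgenome_offsets),
            copy_offsets={int(k): v for k, v in dict(config.copy_offsets).items()})
    elif config.methylation_model == "genome_two_point":
        model = MethylationModel.genome_two_point(config.p_cg, config.p_chg,
                                                  config.p_chh)
    else:
        raise ValueError(f"unknown methylation model {config.methylation_model!r}")
    _stage("simulate_methylome")
    truth = generate_methylome(ref, ann, model, seed=seeds[1])

    _stage("variants")
    sample_ref, variants_true = apply_variants(ref, config.snp_rate, seed=seeds[2])
    report.record("variants", simulated_snps=len(variants_true))

    _stage("digest")
    fragments = double_digest(sample_ref)
    selected = select_representation(fragments, config.digest)
    capture = capture_stats(selected, ref, ann, read_len=config.keep_len)
    report.record("digest", fragments=len(fragments), selected=len(selected))

    _stage("simulate_reads")
    rrbs = simulate_rrbs_reads(sample_ref, truth, selected,
                               replace(config.readsim, seed=seeds[3]))
    ddrad = simulate_ddrad_reads(
        sample_ref, selected,
        replace(config.readsim, coverage_target=config.ddrad_coverage,
                seed=seeds[4]))
    report.record("simulate_reads", rrbs_pairs=len(rrbs.pairs),
                  ddrad_pairs=len(ddrad.pairs),
                  rrbs_skipped_fragments=rrbs.skipped_fragments)

    _stage("preprocess")
    bs_pairs, bs_log = preprocess_pairs(rrbs.pairs, keep_len=config.keep_len,
                                        max_low_frac=config.max_low_frac,
                                        min_q=config.min_q)
    dd_pairs, dd_log = preprocess_pairs(ddrad.pairs, keep_len=config.keep_len,
                                        max_low_frac=config.max_low_frac,
                                        min_q=config.min_q)
    report.record("preprocess_rrbs", **bs_log)
    report.record("preprocess_ddrad", **dd_log)

    _stage("align")
    index = build_bs_index(ref, k=config.index_k)
    if config.truth_mode:
        bs_records = place_by_provenance(bs_pairs, index)
        dd_records = place_by_provenance(dd_pairs, index)
        bs_stats = {"input_pairs": len(bs_pairs), "aligned": len(bs_records),
                    "unplaced": len(bs_pairs) - len(bs_records)}
        dd_stats = {"input_pairs": len(dd_pairs), "aligned": len(dd_records),
                    "unplaced": len(dd_pairs) - len(dd_records)}
    else:
        bs_records, bs_stats = align_reads(bs_pairs, index, mode="bisulfite",
                                           max_mm=config.max_mm,
                                           max_span=config.max_span)
        dd_records, dd_stats = align_reads(dd_pairs, index, mode="plain",
                                           max_mm=config.max_mm,
                                           max_span=config.max_span)
    report.record("align_rrbs", **bs_stats)
    report.record("align_ddrad", **dd_stats)

    _stage("call")
    catalog = classify_cytosines(ref)
    counts = pileup(bs_records, catalog, ref, min_baseq=config.min_baseq)
    calls = call_levels(counts, catalog, min_depth=config.min_depth)
    report.record("call", called_sites=len(calls))

    _stage("mask")
    snps = call_snps(dd_records, ref, min_baseq=config.min_baseq, min_alt_count=1)
    masked_calls, removed = mask_sites(calls, snps)
    report.record("mask", candidate_snps=len(snps), **{
        f"removed_{k}": v for k, v in removed.items()})

    _stage("profiles")
    windows = window_profile(masked_calls, ref, ann, config.win, config.step)
    components = component_means(masked_calls, ann, config.flank, config.promoter)
    metagene_genes, excl_g = metagene_profile(masked_calls, ann.genes,
                                              config.flank, config.body_bins,
                                              config.flank_bin)
    metagene_tes, excl_t = metagene_profile(masked_calls, ann.tes, config.flank,
                                            config.body_bins, config.flank_bin)
    histogram, extremes = level_histogram(masked_calls)
    report.record("profiles", windows=len(windows),
                  short_genes_excluded=excl_g, short_tes_excluded=excl_t)

    _stage("stratify")
    expression = generate_expression(ann, truth,
                                     replace(config.expression, seed=seeds[5]))
    classes = bin_expression(expression, config.rpkm_low, config.rpkm_high)
    sub_summary, sub_unlabeled = stratum_means(masked_calls, ann, "subgenome",
                                               config.flank, config.promoter)
    copy_summary, copy_unlabeled = stratum_means(masked_calls, ann, "copy_class",
                                                 config.flank, config.promoter)
    sub_tests = stratum_pairwise_tests(sub_summary)
    copy_tests = stratum_pairwise_tests(copy_summary)
    sub_crosstab, _ = expression_crosstab(classes, ann, "subgenome",
                                          alpha=config.chi2_alpha)
    copy_crosstab, _ = expression_crosstab(classes, ann, "copy_class",
                                           alpha=config.chi2_alpha)
    association = methylation_expression_association(masked_calls, ann, classes)
    report.record("stratify", unlabeled_subgenome=sub_unlabeled,
                  unlabeled_copy=copy_unlabeled)

    result = PipelineResult(
        config=config, report=report, ref=ref, ann=ann, truth=truth,
        sample_ref=sample_ref, variants_true=variants_true,
        fragments=fragments, selected=selected, capture=capture, calls=calls,
        masked_calls=masked_calls, snps=snps, windows=windows,
        components=components, metagene_genes=metagene_genes,
        metagene_tes=metagene_tes, histogram=histogram, extremes=extremes,
        expression=expression, classes=classes,
        subgenome_summary=sub_summary, copy_summary=copy_summary,
        subgenome_tests=sub_tests, copy_tests=copy_tests,
        subgenome_crosstab=sub_crosstab, copy_crosstab=copy_crosstab,
        association=association)
    if outdir is not None:
        _stage("write_outputs")
        _write_outputs(result, Path(outdir))
    return result


def _write_outputs(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    rep = result.report
    mio.write_fasta(result.ref, outdir / "reference.fa")
    mio.write_fasta(result.sample_ref, outdir / "sample.fa")
    mio.write_annotation_gff3(result.ann, outdir / "annotation.gff3")
    if len(result.ann.repeats):
        mio.write_bed(result.ann.repeats, outdir / "repeats.bed", "repeat_id")
    mio.write_fragments_bed(result.selected, outdir / "representation.bed")
    mio.write_tsv(result.capture, outdir / "capture_stats.tsv")
    mio.write_tsv(result.truth.to_frame(), outdir / "methylome_truth.tsv")
    if len(result.variants_true):
        mio.write_vcf(result.variants_true, result.ref, outdir / "variants_true.vcf")
    if len(result.snps):
        mio.write_vcf(result.snps, result.ref, outdir / "snps_called.vcf")
    mio.write_tsv(result.calls, outdir / "site_calls.tsv")
    mio.write_tsv(result.masked_calls, outdir / "site_calls_masked.tsv")
    mio.write_bedgraph(result.masked_calls, outdir / "levels_CG.bedgraph", "CG")
    mio.write_tsv(result.windows, outdir / "window_profile.tsv")
    for ctx in ("CG", "CHG", "CHH"):
        sub = result.windows.dropna(subset=[f"{ctx}_mean"])
        with open(outdir / f"windows_{ctx}.bedgraph", "w") as fh:
            for r in sub.itertuples(index=False):
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t"
                         f"{getattr(r, f'{ctx}_mean'):.4f}\n")
    mio.write_tsv(result.components, outdir / "component_means.tsv")
    mio.write_tsv(result.metagene_genes, outdir / "metagene_genes.tsv")
    mio.write_tsv(result.metagene_tes, outdir / "metagene_tes.tsv")
    mio.write_tsv(result.histogram, outdir / "level_histogram.tsv")
    mio.write_tsv(result.expression, outdir / "expression.tsv")
    mio.write_tsv(result.classes, outdir / "expression_classes.tsv")
    mio.write_tsv(result.subgenome_summary, outdir / "subgenome_summary.tsv")
    mio.write_tsv(result.copy_summary, outdir / "copy_summary.tsv")
    mio.write_tsv(result.subgenome_tests, outdir / "subgenome_tests.tsv")
    mio.write_tsv(result.copy_tests, outdir / "copy_tests.tsv")
    mio.write_tsv(result.subgenome_crosstab, outdir / "subgenome_expression.tsv")
    mio.write_tsv(result.copy_crosstab, outdir / "copy_expression.tsv")
    mio.write_tsv(result.association.table, outdir / "methylation_vs_expression.tsv")
    (outdir / "report.json").write_text(rep.to_json())
    (outdir / "report.md").write_text(_markdown_report(result))
    for name in ("reference.fa", "annotation.gff3", "site_calls_masked.tsv",
                 "report.json"):
        rep.outputs[name] = str(outdir / name)


def _markdown_report(result: PipelineResult) -> str:
    lines = ["# mRRBS run report", ""]
    for stage, counters in result.report.stages.items():
        lines.append(f"## {stage}")
        for k, v in counters.items():
            lines.append(f"- {k}: {v}")
        lines.append("")
    lines.append("## capture")
    lines.append(result.capture.to_string(index=False))
    lines.append("")
    lines.append("## component means")
    lines.append(result.components.to_string(index=False))
    lines.append("")
    lines.append("## subgenome pairwise tests (genic CG)")
    lines.append(result.subgenome_tests.to_string(index=False))
    lines.append("")
    return "\n".join(lines) + "\n"
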