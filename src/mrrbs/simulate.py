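"""Synthetic genomes, methylomes, variants, reads and expression tables.

The generator emulates the statistical structure the downstream analysis
assumes: a multi-chromosome genome whose central (pericentromere-like)
block is TE- and repeat-dense, gene models with exon/intron structure
carrying subgenome (LF/MF1/MF2) and copy-number (1/2/3) labels, a
ground-truth methylome with context- and component-dependent levels
(CG >= CHG >= CHH everywhere; TE > intron > exon), sample-vs-reference
SNPs, non-directional PE100 bisulfite reads from size-selected double
digestion fragments, parallel non-bisulfite (ddRAD) reads, and an
expression table negatively coupled to genic methylation.

Every generator is a pure function of its inputs and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _seq
from .digest import Fragment
from .genome import (COPY_CLASSES, EXON_COLUMNS, GENE_COLUMNS, REPEAT_COLUMNS,
                     SUBGENOMES, TE_COLUMNS, AnnotationSet, ReferenceSet)
from .methcall import CONTEXT_CODES, classify_cytosines
from .preprocess import ReadPair

# methylation components in increasing priority; later entries win overlaps
COMPONENTS = ("intergenic", "flank", "promoter", "intron", "exon", "te")
COMP_INDEX = {name: i for i, name in enumerate(COMPONENTS)}


class PackingError(ValueError):
    """Requested features do not fit inside the chromosome."""


# ---------------------------------------------------------------------------
# genome


@dataclass(frozen=True)
class GenomeSpec:
    """Shape parameters of the synthetic genome.

    Defaults describe the standard desk-scale study genome: ~2.4 Mb over
    four chromosomes at 45% GC, 260 genes in the chromosome arms, 380 TEs
    of which 70% sit in the central TE-dense block, plus tandem/inverted
    repeat tracks.
    """

    n_chromosomes: int = 4
    chrom_length: int = 600_000
    chrom_lengths: tuple[int, ...] | None = None  # overrides chrom_length
    gc_content: float = 0.45
    n_genes: int = 260
    n_tes: int = 380
    te_pericentromeric_fraction: float = 0.7
    central_block_fraction: float = 0.3
    n_tandem_repeats: int = 40
    n_inverted_repeats: int = 30
    min_gene_gap: int = 2_400
    seed: int = 0

    def __post_init__(self) -> None:
        if self.chrom_lengths is not None:
            object.__setattr__(self, "chrom_lengths", tuple(self.chrom_lengths))
            object.__setattr__(self, "n_chromosomes", len(self.chrom_lengths))
        if min(self.lengths()) <= 0 or self.n_chromosomes <= 0:
            raise ValueError("chromosome count and length must be positive")
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError("gc_content must lie in (0, 1)")
        if not 0.0 <= self.te_pericentromeric_fraction <= 1.0:
            raise ValueError("te_pericentromeric_fraction must lie in [0, 1]")
        if min(self.n_genes, self.n_tes, self.n_tandem_repeats,
               self.n_inverted_repeats) < 0:
            raise ValueError("feature counts must be non-negative")

    def lengths(self) -> tuple[int, ...]:
        if self.chrom_lengths is not None:
            return self.chrom_lengths
        return (self.chrom_length,) * self.n_chromosomes

    def central_block(self, length: int) -> tuple[int, int]:
        half = self.central_block_fraction / 2.0
        return int(length * (0.5 - half)), int(length * (0.5 + half))


def _place_lengths(rng: np.random.Generator, intervals: list[tuple[int, int]],
                   lengths: list[int],
                   ) -> tuple[list[int], list[tuple[int, int]]]:
    """Place blocks of the given lengths inside disjoint free intervals.

    Blocks are assigned largest-first to the interval with the most
    remaining capacity, then laid out within each interval with randomly
    spread slack. Returns block starts (aligned with ``lengths``) and the
    leftover free intervals; raises :class:`PackingError` when a block does
    not fit.
    """
    intervals = [(s, e) for s, e in intervals if e > s]
    remaining = [e - s for s, e in intervals]
    assigned: list[list[int]] = [[] for _ in intervals]
    order = sorted(range(len(lengths)), key=lambda i: -lengths[i])
    for i in order:
        if not remaining:
            raise PackingError("no free space left")
        j = int(np.argmax(remaining))
        if remaining[j] < lengths[i]:
            raise PackingError(f"block of {lengths[i]} bp does not fit")
        assigned[j].append(i)
        remaining[j] -= lengths[i]
    starts = [0] * len(lengths)
    free: list[tuple[int, int]] = []
    for (s, e), items in zip(intervals, assigned):
        rng.shuffle(items)
        block_starts, gaps = _layout_sequential(rng, s, e,
                                                [lengths[i] for i in items])
        free.extend(gaps)
        for pos, i in zip(block_starts, items):
            starts[i] = pos
    return starts, free


def _gene_structure(rng: np.random.Generator) -> tuple[int, list[int], list[int]]:
    n_exons = 1 + int(rng.poisson(3))
    exon_lens = np.clip(rng.lognormal(np.log(250), 0.5, n_exons), 60, 2000).astype(int)
    intron_lens = rng.integers(100, 600, max(n_exons - 1, 0))
    return n_exons, list(exon_lens), list(intron_lens)


def _layout_sequential(rng: np.random.Generator, start: int, end: int,
                       lengths: list[int]) -> tuple[list[int], list[tuple[int, int]]]:
    """Place blocks in order inside [start, end), spreading the slack as
    random gaps; returns block starts and the leftover gap intervals."""
    total = sum(lengths)
    slack = (end - start) - total
    if slack < 0:
        raise PackingError(f"{total} bp of features exceed {end - start} bp of space")
    gaps = rng.multinomial(slack, np.full(len(lengths) + 1, 1.0 / (len(lengths) + 1)))
    starts, free = [], []
    cursor = start
    for g, ln in zip(gaps[:-1], lengths):
        if g > 0:
            free.append((cursor, cursor + int(g)))
        cursor += int(g)
        starts.append(cursor)
        cursor += ln
    if gaps[-1] > 0:
        free.append((cursor, cursor + int(gaps[-1])))
    return starts, free


def generate_genome(spec: GenomeSpec) -> tuple[ReferenceSet, AnnotationSet]:
    """Build the reference sequences and annotation tables for a spec."""
    rng = np.random.default_rng(spec.seed)
    sequences: dict[str, str] = {}
    genes, exons, tes, repeats = [], [], [], []
    gene_serial = te_serial = rep_serial = 0

    chrom_names = [f"chr{i + 1}" for i in range(spec.n_chromosomes)]
    per_chrom_genes = _split_count(spec.n_genes, spec.n_chromosomes)
    per_chrom_tes = _split_count(spec.n_tes, spec.n_chromosomes)
    per_chrom_tr = _split_count(spec.n_tandem_repeats, spec.n_chromosomes)
    per_chrom_ir = _split_count(spec.n_inverted_repeats, spec.n_chromosomes)

    for ci, chrom in enumerate(chrom_names):
        L = spec.lengths()[ci]
        arr = _seq.random_bases(rng, L, spec.gc_content)
        b_start, b_end = spec.central_block(L)

        # build the item lists: genes reserve their body plus a gap that
        # leaves room for the 1-kb flanks; TEs and repeat tracks take their
        # own length. The pericentromeric TE share and ~70% of repeats go
        # into the central block, everything else into the two arms.
        items: list[tuple[str, object, int]] = []  # (kind, payload, length)
        for _ in range(per_chrom_genes[ci]):
            st = _gene_structure(rng)
            body = sum(st[1]) + sum(st[2])
            items.append(("gene", st, body + spec.min_gene_gap))
        n_central_te = int(round(per_chrom_tes[ci]
                                 * spec.te_pericentromeric_fraction))
        te_lens = [int(np.clip(rng.lognormal(np.log(900), 0.6), 150, 5000))
                   for _ in range(per_chrom_tes[ci])]
        for j, te_len in enumerate(te_lens):
            items.append(("te_central" if j < n_central_te else "te",
                          None, te_len))
        for kind, count in (("tandem", per_chrom_tr[ci]),
                            ("inverted", per_chrom_ir[ci])):
            for _ in range(count):
                if kind == "tandem":
                    track_len = int(rng.integers(300, 1200))
                    motif = _seq.random_bases(rng, int(rng.integers(2, 11)),
                                              spec.gc_content)
                    unit = np.tile(motif, track_len // len(motif) + 1)[:track_len]
                else:
                    arm_len = int(rng.integers(50, 300))
                    spacer = int(rng.integers(20, 100))
                    a = _seq.random_bases(rng, arm_len, spec.gc_content)
                    unit = np.concatenate([
                        a, _seq.random_bases(rng, spacer, spec.gc_content),
                        _seq.revcomp_arr(a)])
                where = "repeat_central" if rng.random() < 0.7 else "repeat"
                items.append((where, (kind, unit), len(unit)))

        # assign to compartments by remaining capacity, then lay each
        # compartment out with randomly spread slack
        compartments = [(0, b_start), (b_end, L), (b_start, b_end)]  # arms, block
        remaining = [max(e - s, 0) for s, e in compartments]
        assigned: list[list[tuple[str, object, int]]] = [[], [], []]
        for kind, payload, length in items:
            if kind == "te_central":
                choices = [2]  # pericentromeric TEs never spill into arms
                kind = "te"
            elif kind == "repeat_central":
                choices = [2, 0, 1]
                kind = "repeat"
            elif kind == "gene":
                choices = [0, 1] if remaining[0] >= remaining[1] else [1, 0]
            else:
                choices = ([0, 1, 2] if remaining[0] >= remaining[1]
                           else [1, 0, 2])
            target = next((t for t in choices if remaining[t] >= length), None)
            if target is None:
                raise PackingError(f"cannot place {kind} of {length} bp on {chrom}")
            assigned[target].append((kind, payload, length))
            remaining[target] -= length
        for (c_s, c_e), placed in zip(compartments, assigned):
            rng.shuffle(placed)
            starts, _ = _layout_sequential(rng, c_s, c_e,
                                           [ln for _, _, ln in placed])
            for pos, (kind, payload, length) in zip(starts, placed):
                if kind == "gene":
                    n_exons, exon_lens, intron_lens = payload
                    body = sum(exon_lens) + sum(intron_lens)
                    gstart = pos + spec.min_gene_gap // 2
                    strand = "+" if rng.random() < 0.5 else "-"
                    sub = SUBGENOMES[rng.choice(3, p=[0.46, 0.30, 0.24])]
                    copy = COPY_CLASSES[rng.choice(3, p=[0.40, 0.35, 0.25])]
                    gid = f"g{gene_serial:05d}"
                    gene_serial += 1
                    genes.append((gid, chrom, gstart, gstart + body, strand,
                                  sub, copy))
                    cursor = gstart
                    for i in range(n_exons):
                        exons.append((gid, chrom, cursor,
                                      cursor + exon_lens[i], strand))
                        cursor += exon_lens[i]
                        if i < n_exons - 1:
                            cursor += intron_lens[i]
                elif kind == "te":
                    strand = "+" if rng.random() < 0.5 else "-"
                    tes.append((f"te{te_serial:05d}", chrom, pos, pos + length,
                                strand))
                    te_serial += 1
                else:
                    rep_kind, unit = payload
                    arr[pos:pos + length] = unit
                    repeats.append((f"{rep_kind[:2]}{rep_serial:05d}", chrom,
                                    pos, pos + length, rep_kind))
                    rep_serial += 1

        sequences[chrom] = _seq.decode(arr)

    ann = AnnotationSet(
        genes=pd.DataFrame(genes, columns=GENE_COLUMNS),
        exons=pd.DataFrame(exons, columns=EXON_COLUMNS),
        tes=pd.DataFrame(tes, columns=TE_COLUMNS),
        repeats=pd.DataFrame(repeats, columns=REPEAT_COLUMNS),
    )
    ref = ReferenceSet(sequences)
    ann.validate(ref)
    return ref, ann


def _split_count(total: int, parts: int) -> list[int]:
    base = total // parts
    out = [base] * parts
    for i in range(total - base * parts):
        out[i] += 1
    return out


# ---------------------------------------------------------------------------
# methylome


@dataclass
class MethylationModel:
    """Mean methylation level and distribution family per component x context.

    ``means[(component, context)]`` are probabilities in [0, 1]; ``family``
    is ``beta`` (spread ``beta_concentration``) or ``two_point`` ({0,1}
    mixture whose weight is the mean). ``subgenome_offsets``/``copy_offsets``
    shift the genic components (flank/promoter/intron/exon) of genes in the
    given stratum.
    """

    means: dict[tuple[str, str], float]
    family: dict[tuple[str, str], str] = field(default_factory=dict)
    beta_concentration: float = 50.0
    subgenome_offsets: dict[str, float] = field(default_factory=dict)
    copy_offsets: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, m in self.means.items():
            if not 0.0 <= m <= 1.0:
                raise ValueError(f"mean out of [0,1] for {key}")
        for comp in {c for c, _ in self.means}:
            cg = self.means.get((comp, "CG"))
            chg = self.means.get((comp, "CHG"))
            chh = self.means.get((comp, "CHH"))
            if None not in (cg, chg, chh) and not cg >= chg >= chh:
                raise ValueError(f"context ordering CG>=CHG>=CHH violated in {comp}")

    def family_of(self, comp: str, ctx: str) -> str:
        return self.family.get((comp, ctx), "beta")

    @classmethod
    def component_default(cls,
                          subgenome_offsets: dict[str, float] | None = None,
                          copy_offsets: dict[int, float] | None = None,
                          ) -> "MethylationModel":
        """Component-specific means: highly methylated TE bodies, bimodally
        ordered genic components, intermediate CHG and low CHH throughout."""
        means = {
            ("te", "CG"): 0.880, ("te", "CHG"): 0.540, ("te", "CHH"): 0.177,
            ("intron", "CG"): 0.544, ("intron", "CHG"): 0.220, ("intron", "CHH"): 0.059,
            ("exon", "CG"): 0.251, ("exon", "CHG"): 0.088, ("exon", "CHH"): 0.027,
            ("promoter", "CG"): 0.250, ("promoter", "CHG"): 0.090, ("promoter", "CHH"): 0.030,
            ("flank", "CG"): 0.400, ("flank", "CHG"): 0.150, ("flank", "CHH"): 0.050,
            ("intergenic", "CG"): 0.650, ("intergenic", "CHG"): 0.400, ("intergenic", "CHH"): 0.100,
        }
        return cls(means=means,
                   subgenome_offsets=subgenome_offsets or {},
                   copy_offsets=copy_offsets or {})

    @classmethod
    def genome_two_point(cls, p_cg: float = 0.524, p_chg: float = 0.318,
                         p_chh: float = 0.083) -> "MethylationModel":
        """Uniform genome-wide two-point {0,1} site mixture per context."""
        means = {}
        family = {}
        for comp in COMPONENTS:
            for ctx, p in (("CG", p_cg), ("CHG", p_chg), ("CHH", p_chh)):
                means[(comp, ctx)] = p
                family[(comp, ctx)] = "two_point"
        return cls(means=means, family=family)


@dataclass
class MethylomeTruth:
    """Dense per-position ground-truth methylation levels for both strands.

    ``levels_top[chrom][p]`` is the true level of the top-strand cytosine at
    p (NaN where the base is not C); ``contexts_*`` carry the matching
    context codes. ``component``/``gene_index`` record the component map the
    levels were drawn from.
    """

    levels_top: dict[str, np.ndarray]
    levels_bottom: dict[str, np.ndarray]
    contexts_top: dict[str, np.ndarray]
    contexts_bottom: dict[str, np.ndarray]
    component: dict[str, np.ndarray]
    gene_index: dict[str, np.ndarray]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for strand, levels, contexts in (("+", self.levels_top, self.contexts_top),
                                         ("-", self.levels_bottom, self.contexts_bottom)):
            for chrom, lv in levels.items():
                pos = np.flatnonzero(~np.isnan(lv))
                ctx = contexts[chrom][pos]
                from .methcall import CONTEXT_NAMES
                rows.append(pd.DataFrame({
                    "chrom": chrom, "pos": pos, "strand": strand,
                    "context": pd.Series(ctx).map(CONTEXT_NAMES),
                    "level": lv[pos],
                }))
        df = pd.concat(rows, ignore_index=True)
        return df.sort_values(["chrom", "pos", "strand"]).reset_index(drop=True)

    def mean_by_component_context(self) -> pd.DataFrame:
        """Empirical truth means per component x context (site-weighted)."""
        records = []
        for strand, levels, contexts in (("+", self.levels_top, self.contexts_top),
                                         ("-", self.levels_bottom, self.contexts_bottom)):
            for chrom, lv in levels.items():
                pos = np.flatnonzero(~np.isnan(lv))
                records.append(pd.DataFrame({
                    "component": pd.Series(self.component[chrom][pos]).map(
                        dict(enumerate(COMPONENTS))),
                    "context": contexts[chrom][pos],
                    "level": lv[pos],
                }))
        df = pd.concat(records, ignore_index=True)
        from .methcall import CONTEXT_NAMES
        df["context"] = df["context"].map(CONTEXT_NAMES)
        return (df.groupby(["component", "context"])["level"]
                  .agg(["mean", "count"]).reset_index())


def _component_maps(ref: ReferenceSet, ann: AnnotationSet, flank: int = 1000,
                    promoter: int = 200) -> tuple[dict[str, np.ndarray],
                                                  dict[str, np.ndarray]]:
    """Paint the per-position component and owning-gene maps.

    Painting order encodes overlap priority (TE > exon > intron > promoter >
    flank > intergenic).
    """
    comp = {c: np.zeros(ref.length(c), dtype=np.uint8) for c in ref.names()}
    gidx = {c: np.full(ref.length(c), -1, dtype=np.int32) for c in ref.names()}

    def paint(chrom, start, end, code, gene_i):
        L = ref.length(chrom)
        s, e = max(start, 0), min(end, L)
        if e > s:
            comp[chrom][s:e] = code
            gidx[chrom][s:e] = gene_i

    for i, g in enumerate(ann.genes.itertuples(index=False)):
        if g.strand == "+":
            paint(g.chrom, g.start - flank, g.start, COMP_INDEX["flank"], i)
            paint(g.chrom, g.end, g.end + flank, COMP_INDEX["flank"], i)
            paint(g.chrom, g.start - promoter, g.start, COMP_INDEX["promoter"], i)
        else:
            paint(g.chrom, g.end, g.end + flank, COMP_INDEX["flank"], i)
            paint(g.chrom, g.start - flank, g.start, COMP_INDEX["flank"], i)
            paint(g.chrom, g.end, g.end + promoter, COMP_INDEX["promoter"], i)
    for i, g in enumerate(ann.genes.itertuples(index=False)):
        paint(g.chrom, g.start, g.end, COMP_INDEX["intron"], i)
    for e in ann.exons.itertuples(index=False):
        gene_i = int(ann.genes.index[ann.genes["gene_id"] == e.gene_id][0])
        paint(e.chrom, e.start, e.end, COMP_INDEX["exon"], gene_i)
    for t in ann.tes.itertuples(index=False):
        paint(t.chrom, t.start, t.end, COMP_INDEX["te"], -1)
    return comp, gidx


def generate_methylome(ref: ReferenceSet, ann: AnnotationSet,
                       model: MethylationModel, seed: int = 0) -> MethylomeTruth:
    """Draw one true methylation level per cytosine on both strands."""
    rng = np.random.default_rng(seed)
    catalog = classify_cytosines(ref)
    comp, gidx = _component_maps(ref, ann)

    base_mean = np.zeros((len(COMPONENTS), 4), dtype=np.float64)
    fam_two_point = np.zeros((len(COMPONENTS), 4), dtype=bool)
    for ci, cname in enumerate(COMPONENTS):
        for ctx_name, ctx_code in CONTEXT_CODES.items():
            if (cname, ctx_name) not in model.means:
                raise KeyError(f"model lacks mean for ({cname}, {ctx_name})")
            base_mean[ci, ctx_code] = model.means[(cname, ctx_name)]
            fam_two_point[ci, ctx_code] = model.family_of(cname, ctx_name) == "two_point"

    gene_offset = np.zeros(max(len(ann.genes), 1), dtype=np.float64)
    for i, g in enumerate(ann.genes.itertuples(index=False)):
        gene_offset[i] = (model.subgenome_offsets.get(g.subgenome, 0.0)
                          + model.copy_offsets.get(g.copy_class, 0.0))

    levels_top, levels_bottom = {}, {}
    for chrom in ref.names():
        for levels_d, ctx_arr in ((levels_top, catalog.top[chrom]),
                                  (levels_bottom, catalog.bottom[chrom])):
            lv = np.full(ref.length(chrom), np.nan, dtype=np.float32)
            sites = np.flatnonzero(ctx_arr)
            if len(sites):
                c = comp[chrom][sites]
                x = ctx_arr[sites]
                mean = base_mean[c, x]
                gi = gidx[chrom][sites]
                mean = mean + np.where(gi >= 0, gene_offset[np.maximum(gi, 0)], 0.0)
                mean = np.clip(mean, 0.0, 1.0)
                two = fam_two_point[c, x]
                draw = np.empty(len(sites), dtype=np.float64)
                if two.any():
                    draw[two] = (rng.random(int(two.sum())) < mean[two]).astype(float)
                beta = ~two
                if beta.any():
                    nu = model.beta_concentration
                    # degenerate means stay exact; interior means draw Beta
                    m = np.clip(mean[beta], 1e-6, 1 - 1e-6)
                    d = rng.beta(m * nu, (1 - m) * nu)
                    d[mean[beta] == 0.0] = 0.0
                    d[mean[beta] == 1.0] = 1.0
                    draw[beta] = d
                lv[sites] = draw
            levels_d[chrom] = lv

    return MethylomeTruth(
        levels_top=levels_top, levels_bottom=levels_bottom,
        contexts_top=catalog.top, contexts_bottom=catalog.bottom,
        component=comp, gene_index=gidx,
    )


# ---------------------------------------------------------------------------
# variants


def apply_variants(ref: ReferenceSet, snp_rate: float, seed: int = 0,
                   ) -> tuple[ReferenceSet, pd.DataFrame]:
    """Substitute bases at rate ``snp_rate`` to derive the sample genome.

    Returns the mutated genome and the variant table (chrom, pos, ref, alt);
    the sample differs from the reference exactly at the listed positions.
    """
    if not 0.0 <= snp_rate < 1.0:
        raise ValueError("snp_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    sequences = {}
    rows = []
    for chrom in ref.names():
        arr = ref.encoded(chrom).copy()
        hit = np.flatnonzero(rng.random(len(arr)) < snp_rate)
        hit = hit[arr[hit] != _seq.N]
        if len(hit):
            shift = rng.integers(1, 4, len(hit)).astype(np.uint8)
            alt = (arr[hit] + shift) % 4
            for p, r, a in zip(hit, arr[hit], alt):
                rows.append((chrom, int(p), "ACGT"[r], "ACGT"[a]))
            arr[hit] = alt
        sequences[chrom] = _seq.decode(arr)
    variants = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    return ReferenceSet(sequences), variants


# ---------------------------------------------------------------------------
# reads


@dataclass(frozen=True)
class ReadSimParams:
    """Sequencing model: PE100 reads taken from fragment ends inward.

    ``coverage_target`` is the expected informative coverage per captured
    cytosine site. A non-directional molecule reports the cytosines of one
    strand only, so the simulator samples ``2 x coverage_target`` pairs per
    retained fragment (raw pileup depth is therefore about twice the site
    coverage). Conversion acts per molecule: each cytosine's methylation
    status is drawn once per sampled fragment molecule so mates stay
    consistent.
    """

    raw_read_length: int = 100
    coverage_target: float = 20.0
    bisulfite_conversion_efficiency: float = 0.995
    sequencing_error_rate: float = 0.001
    quality_mean: float = 38.0
    quality_sd: float = 3.0
    degraded_fraction: float = 0.02
    degraded_quality_mean: float = 25.0
    min_fragment_length: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.bisulfite_conversion_efficiency, self.sequencing_error_rate,
                  self.degraded_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.raw_read_length <= 0:
            raise ValueError("raw_read_length must be positive")


@dataclass
class SimulatedReads:
    pairs: list[ReadPair]
    skipped_fragments: int


def _qualities(rng: np.random.Generator, n: int, params: ReadSimParams) -> np.ndarray:
    mean = (params.degraded_quality_mean
            if rng.random() < params.degraded_fraction else params.quality_mean)
    q = np.rint(rng.normal(mean, params.quality_sd, n))
    return np.clip(q, 2, 40).astype(np.int16)


def _apply_errors(rng: np.random.Generator, arr: np.ndarray, rate: float) -> np.ndarray:
    if rate <= 0:
        return arr
    hit = np.flatnonzero(rng.random(len(arr)) < rate)
    if len(hit):
        arr = arr.copy()
        arr[hit] = (arr[hit] + rng.integers(1, 4, len(hit)).astype(np.uint8)) % 4
    return arr


def _emit_pair(rng, name, strand_a, strand_b, r1_from_a, params) -> ReadPair:
    n = params.raw_read_length
    r1 = (strand_a if r1_from_a else strand_b)[:n]
    r2 = (strand_b if r1_from_a else strand_a)[:n]
    r1 = _apply_errors(rng, r1, params.sequencing_error_rate)
    r2 = _apply_errors(rng, r2, params.sequencing_error_rate)
    q1 = _qualities(rng, len(r1), params)
    q2 = _qualities(rng, len(r2), params)
    return ReadPair(name, _seq.decode(r1), _seq.array_to_phred(q1),
                    _seq.decode(r2), _seq.array_to_phred(q2))


def simulate_rrbs_reads(sample_ref: ReferenceSet, truth: MethylomeTruth,
                        fragments: list[Fragment], params: ReadSimParams,
                        ) -> SimulatedReads:
    """Non-directional paired bisulfite reads from the retained fragments.

    Read names encode ground-truth provenance as
    ``chrom:start:end:strand:bs-strand:serial`` for oracle tests. Cytosines
    on SNP-disrupted sites (no truth level on the sample base) behave as
    unmethylated.
    """
    rng = np.random.default_rng(params.seed)
    pairs: list[ReadPair] = []
    skipped = 0
    serial = 0
    eff = params.bisulfite_conversion_efficiency
    for frag in fragments:
        if frag.length < params.min_fragment_length:
            skipped += 1
            continue
        chrom = frag.chrom
        frag_arr = sample_ref.encoded(chrom)[frag.start:frag.end]
        n_pairs = int(rng.poisson(2.0 * params.coverage_target))
        for _ in range(n_pairs):
            src = "+" if rng.random() < 0.5 else "-"
            if src == "+":
                mol = frag_arr.copy()
                cpos = np.flatnonzero(mol == _seq.C)
                lv = np.nan_to_num(
                    truth.levels_top[chrom][frag.start + cpos].astype(np.float64))
            else:
                mol = _seq.revcomp_arr(frag_arr)
                cpos = np.flatnonzero(mol == _seq.C)
                top_pos = frag.start + (frag.length - 1 - cpos)
                lv = np.nan_to_num(
                    truth.levels_bottom[chrom][top_pos].astype(np.float64))
            meth = rng.random(len(cpos)) < lv
            convert = (~meth) & (rng.random(len(cpos)) < eff)
            mol[cpos[convert]] = _seq.T
            strand_a, strand_b = mol, _seq.revcomp_arr(mol)
            r1_from_a = rng.random() < 0.5
            bs = {("+", True): "OT", ("+", False): "CTOT",
                  ("-", True): "OB", ("-", False): "CTOB"}[(src, r1_from_a)]
            name = f"{chrom}:{frag.start}:{frag.end}:{src}:{bs}:{serial}"
            serial += 1
            pairs.append(_emit_pair(rng, name, strand_a, strand_b, r1_from_a, params))
    return SimulatedReads(pairs=pairs, skipped_fragments=skipped)


def simulate_ddrad_reads(sample_ref: ReferenceSet, fragments: list[Fragment],
                         params: ReadSimParams) -> SimulatedReads:
    """Paired non-bisulfite reads from the same representation."""
    rng = np.random.default_rng(params.seed)
    pairs: list[ReadPair] = []
    skipped = 0
    serial = 0
    for frag in fragments:
        if frag.length < params.min_fragment_length:
            skipped += 1
            continue
        frag_arr = sample_ref.encoded(frag.chrom)[frag.start:frag.end]
        n_pairs = int(rng.poisson(2.0 * params.coverage_target))
        for _ in range(n_pairs):
            src = "+" if rng.random() < 0.5 else "-"
            strand_a = frag_arr if src == "+" else _seq.revcomp_arr(frag_arr)
            strand_b = _seq.revcomp_arr(strand_a)
            name = f"{frag.chrom}:{frag.start}:{frag.end}:{src}:NA:{serial}"
            serial += 1
            pairs.append(_emit_pair(rng, name, strand_a, strand_b, True, params))
    return SimulatedReads(pairs=pairs, skipped_fragments=skipped)


# ---------------------------------------------------------------------------
# expression


@dataclass(frozen=True)
class ExpressionModel:
    """Log-RPKM model with stratum effects and methylation coupling.

    log2(RPKM) = base + subgenome effect + copy effect
                 + coupling * (gene CG methylation - reference level)
                 + Normal(0, dispersion).
    Defaults express the LF > MF2 > MF1 and multi-copy > single-copy
    transcription hierarchy, with a negative methylation coupling.
    """

    base_log2: float = 2.0
    subgenome_effects: tuple[tuple[str, float], ...] = (
        ("LF", 0.8), ("MF1", -0.5), ("MF2", 0.0))
    copy_effects: tuple[tuple[int, float], ...] = ((1, -0.8), (2, 0.2), (3, 0.6))
    dispersion: float = 2.2
    methylation_coupling: float = -3.0
    reference_methylation: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")


def gene_body_cg_methylation(ann: AnnotationSet, truth: MethylomeTruth) -> pd.Series:
    """Mean true CG level over each gene body (both strands); NaN if no site."""
    from .methcall import CONTEXT_CG
    out = {}
    for g in ann.genes.itertuples(index=False):
        vals = []
        for lv, ctx in ((truth.levels_top, truth.contexts_top),
                        (truth.levels_bottom, truth.contexts_bottom)):
            seg = lv[g.chrom][g.start:g.end]
            cseg = ctx[g.chrom][g.start:g.end]
            vals.append(seg[(cseg == CONTEXT_CG) & ~np.isnan(seg)])
        v = np.concatenate(vals)
        out[g.gene_id] = float(v.mean()) if len(v) else np.nan
    return pd.Series(out, name="gene_cg_methylation")


def generate_expression(ann: AnnotationSet, truth: MethylomeTruth,
                        model: ExpressionModel) -> pd.DataFrame:
    """One RPKM value per gene, negatively coupled to genic CG methylation."""
    if len(ann.genes) == 0:
        return pd.DataFrame(columns=["gene_id", "rpkm", "gene_cg_methylation"])
    rng = np.random.default_rng(model.seed)
    meth = gene_body_cg_methylation(ann, truth)
    sub_eff = dict(model.subgenome_effects)
    copy_eff = dict(model.copy_effects)
    rows = []
    for g in ann.genes.itertuples(index=False):
        m = meth[g.gene_id]
        m_term = 0.0 if np.isnan(m) else model.methylation_coupling * (
            m - model.reference_methylation)
        x = (model.base_log2 + sub_eff.get(g.subgenome, 0.0)
             + copy_eff.get(g.copy_class, 0.0) + m_term
             + (rng.normal(0.0, model.dispersion) if model.dispersion > 0 else 0.0))
        rows.append((g.gene_id, float(2.0 ** x), m))
    return pd.DataFrame(rows, columns=["gene_id", "rpkm", "gene_cg_methylation"])
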