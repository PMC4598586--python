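"""Subgenome and copy-number stratification with chi-square comparisons.

Methylation differences between strata are tested on pooled
methylated/unmethylated read counts with a 1-df 2x2 chi-square (no
continuity correction), declared significant above the P = 0.01 critical
value (6.63). Expression classes (RPKM <= 5 low, 5-50 medium, > 50 high)
are compared between strata with a 2-df test on the 3-class count vectors;
compact letters group strata that are not significantly different. No
multiple-testing correction is applied: the significance criterion is the
fixed per-comparison threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome import AnnotationSet
from .profiles import component_intervals, pooled_component_stats

CHI2_CRITICAL_P01 = float(stats.chi2.ppf(0.99, df=1))  # 6.63 at 2 d.p.


def chisq_critical(p: float = 0.01, df: int = 1) -> float:
    """Upper critical value of the chi-square null at tail probability p."""
    return float(stats.chi2.ppf(1.0 - p, df=df))


@dataclass(frozen=True)
class ChisqResult:
    statistic: float
    pvalue: float
    significant: bool
    computable: bool = True


def pairwise_chisq(counts_a: tuple[int, int], counts_b: tuple[int, int],
                   critical: float = CHI2_CRITICAL_P01) -> ChisqResult:
    """1-df 2x2 chi-square on pooled (methylated, unmethylated) counts.

    Uses the closed form N(ad-bc)^2 / (r1 r2 c1 c2) without continuity
    correction; a zero marginal makes the statistic undefined and the
    result not-computable.
    """
    a, b = counts_a
    c, d = counts_b
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    n = r1 + r2
    if 0 in (r1, r2, c1, c2):
        return ChisqResult(float("nan"), float("nan"), False, computable=False)
    stat = n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
    p = float(stats.chi2.sf(stat, df=1))
    return ChisqResult(float(stat), p, bool(stat > critical))


# ---------------------------------------------------------------------------
# stratified methylation


def stratum_means(calls: pd.DataFrame, ann: AnnotationSet, key: str,
                  flank: int = 1000, promoter: int = 200,
                  ) -> tuple[pd.DataFrame, int]:
    """Pooled methylation per stratum x component x context.

    ``key`` is ``subgenome`` or ``copy_class``. Each stratum additionally
    receives ``genic`` rows pooling every component of its gene models
    (upstream, promoter, exon, intron, downstream). Genes without a label
    are excluded; their count is returned.
    """
    if key not in ("subgenome", "copy_class"):
        raise ValueError("key must be 'subgenome' or 'copy_class'")
    genes = ann.genes
    unlabeled = int(genes[key].isna().sum()) if len(genes) else 0
    genes = genes[genes[key].notna()]
    frames = []
    for stratum, sub in genes.groupby(key):
        ivs = component_intervals(ann, flank, promoter, genes=sub)
        ivs.pop("te", None)  # TE bodies are not part of any gene stratum
        df = pooled_component_stats(calls, ivs)
        if len(df) == 0:
            continue
        genic = (df.groupby("context")
                   .agg(n_sites=("n_sites", "sum"),
                        meth_reads=("meth_reads", "sum"),
                        unmeth_reads=("unmeth_reads", "sum"))
                   .reset_index())
        genic["component"] = "genic"
        genic["mean_level"] = np.nan
        genic["read_level"] = genic["meth_reads"] / (
            genic["meth_reads"] + genic["unmeth_reads"])
        df = pd.concat([df, genic[df.columns]], ignore_index=True)
        df.insert(0, "stratum", stratum)
        df.insert(0, "key", key)
        frames.append(df)
    if not frames:
        return pd.DataFrame(columns=["key", "stratum", "component", "context",
                                     "n_sites", "mean_level", "meth_reads",
                                     "unmeth_reads", "read_level"]), unlabeled
    return pd.concat(frames, ignore_index=True), unlabeled


def stratum_pairwise_tests(summary: pd.DataFrame, component: str = "genic",
                           context: str = "CG",
                           critical: float = CHI2_CRITICAL_P01) -> pd.DataFrame:
    """All pairwise 2x2 chi-square tests between strata for one cell."""
    sel = summary[(summary["component"] == component)
                  & (summary["context"] == context)]
    rows = []
    strata = list(sel["stratum"])
    for i in range(len(strata)):
        for j in range(i + 1, len(strata)):
            a = sel.iloc[i]
            b = sel.iloc[j]
            res = pairwise_chisq((int(a["meth_reads"]), int(a["unmeth_reads"])),
                                 (int(b["meth_reads"]), int(b["unmeth_reads"])),
                                 critical)
            rows.append({"stratum_a": a["stratum"], "stratum_b": b["stratum"],
                         "level_a": a["read_level"], "level_b": b["read_level"],
                         "statistic": res.statistic, "pvalue": res.pvalue,
                         "significant": res.significant,
                         "computable": res.computable})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# expression


def bin_expression(expression: pd.DataFrame, low_max: float = 5.0,
                   high_min: float = 50.0) -> pd.DataFrame:
    """Attach transcription classes: low (<= low_max), medium, high (> high_min)."""
    rpkm = expression["rpkm"]
    if (rpkm < 0).any():
        raise ValueError("negative RPKM")
    out = expression.copy()
    out["expr_class"] = np.where(rpkm <= low_max, "low",
                                 np.where(rpkm <= high_min, "medium", "high"))
    return out


def _assign_letters(strata: list[str], high_frac: dict[str, float],
                    different: set[tuple[str, str]]) -> dict[str, str]:
    """Greedy compact-letter grouping: strata not significantly different
    share a letter; ordered by descending high-expression fraction, ties by
    name."""
    order = sorted(strata, key=lambda s: (-high_frac[s], s))
    groups: list[list[str]] = []
    for s in order:
        placed = False
        for grp in groups:
            if all((s, m) not in different and (m, s) not in different for m in grp):
                grp.append(s)
                placed = True
                break
        if not placed:
            groups.append([s])
    letters = {}
    for gi, grp in enumerate(groups):
        for s in grp:
            letters[s] = chr(ord("a") + gi)
    return letters


def expression_crosstab(classes: pd.DataFrame, ann: AnnotationSet, key: str,
                        alpha: float = 0.01) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-stratum expression-class table with pairwise 2-df tests.

    Returns the class table (counts, fractions, significance letter) and
    the pairwise test table.
    """
    merged = classes.merge(ann.genes[["gene_id", key]], on="gene_id")
    merged = merged[merged[key].notna()]
    tab = (merged.groupby([key, "expr_class"]).size()
                 .unstack(fill_value=0)
                 .reindex(columns=["low", "medium", "high"], fill_value=0))
    strata = [str(s) for s in tab.index]
    counts = {str(s): tab.loc[s].to_numpy() for s in tab.index}
    pair_rows = []
    different: set[tuple[str, str]] = set()
    for i in range(len(strata)):
        for j in range(i + 1, len(strata)):
            a, b = strata[i], strata[j]
            table = np.vstack([counts[a], counts[b]])
            keep = table.sum(axis=0) > 0
            res = stats.chi2_contingency(table[:, keep], correction=False)
            sig = bool(res.pvalue < alpha)
            if sig:
                different.add((a, b))
            pair_rows.append({"stratum_a": a, "stratum_b": b,
                              "statistic": float(res.statistic),
                              "df": int(res.dof), "pvalue": float(res.pvalue),
                              "significant": sig})
    high_frac = {s: counts[s][2] / max(counts[s].sum(), 1) for s in strata}
    letters = _assign_letters(strata, high_frac, different)
    rows = []
    for s in strata:
        n = counts[s].sum()
        rows.append({
            "stratum": s, "n_genes": int(n),
            "low": int(counts[s][0]), "medium": int(counts[s][1]),
            "high": int(counts[s][2]),
            "low_fraction": counts[s][0] / n if n else 0.0,
            "medium_fraction": counts[s][1] / n if n else 0.0,
            "high_fraction": counts[s][2] / n if n else 0.0,
            "letter": letters[s],
        })
    return pd.DataFrame(rows), pd.DataFrame(pair_rows)


# ---------------------------------------------------------------------------
# methylation vs expression


@dataclass
class AssociationResult:
    """Per-class genic methylation plus a gene-level rank trend test."""

    table: pd.DataFrame              # expr_class x context mean methylation
    monotone_decreasing: dict[str, bool]
    spearman_rho: float
    spearman_p: float


def gene_called_methylation(calls: pd.DataFrame, ann: AnnotationSet,
                            context: str = "CG") -> pd.Series:
    """Mean called level over each gene body for one context (NaN if none)."""
    by_chrom = {chrom: sub.sort_values("pos")
                for chrom, sub in calls[calls["context"] == context].groupby("chrom")}
    out = {}
    for g in ann.genes.itertuples(index=False):
        sub = by_chrom.get(g.chrom)
        if sub is None:
            out[g.gene_id] = np.nan
            continue
        pos = sub["pos"].to_numpy()
        lo, hi = np.searchsorted(pos, [g.start, g.end])
        lv = sub["level"].to_numpy()[lo:hi]
        out[g.gene_id] = float(lv.mean()) if len(lv) else np.nan
    return pd.Series(out, name=f"gene_{context}_methylation")


def methylation_expression_association(calls: pd.DataFrame, ann: AnnotationSet,
                                       classes: pd.DataFrame) -> AssociationResult:
    """Mean genic methylation per expression class, with monotonicity flags.

    The per-class means pool the called sites of all genes in the class
    (per context); the trend test is a gene-level Spearman correlation of
    CG methylation against RPKM.
    """
    order = ["low", "medium", "high"]
    rows = []
    mono: dict[str, bool] = {}
    for ctx in ("CG", "CHG", "CHH"):
        class_means = {}
        for cls in order:
            genes_cls = ann.genes.merge(
                classes.loc[classes["expr_class"] == cls, ["gene_id"]], on="gene_id")
            if len(genes_cls) == 0:
                continue
            ivs = component_intervals(ann, genes=genes_cls)
            for comp in ("upstream", "promoter", "downstream", "te"):
                ivs.pop(comp, None)  # gene body only
            df = pooled_component_stats(calls[calls["context"] == ctx], ivs)
            if len(df) == 0:
                continue
            m = int(df["meth_reads"].sum())
            u = int(df["unmeth_reads"].sum())
            n_sites = int(df["n_sites"].sum())
            site_mean = float(np.average(df["mean_level"], weights=df["n_sites"]))
            class_means[cls] = site_mean
            rows.append({"expr_class": cls, "context": ctx,
                         "mean_level": site_mean, "n_sites": n_sites,
                         "meth_reads": m, "unmeth_reads": u})
        present = [class_means[c] for c in order if c in class_means]
        mono[ctx] = all(x >= y for x, y in zip(present, present[1:])) and len(present) > 1
    gene_meth = gene_called_methylation(calls, ann, "CG")
    merged = classes.merge(gene_meth.rename("meth"), left_on="gene_id",
                           right_index=True)
    merged = merged.dropna(subset=["meth"])
    if len(merged) >= 3 and merged["meth"].nunique() > 1:
        rho, p = stats.spearmanr(merged["meth"], merged["rpkm"])
    else:
        rho, p = float("nan"), float("nan")
    table = pd.DataFrame(rows, columns=["expr_class", "context", "mean_level",
                                        "n_sites", "meth_reads", "unmeth_reads"])
    return AssociationResult(table=table, monotone_decreasing=mono,
                             spearman_rho=float(rho), spearman_p=float(p))
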