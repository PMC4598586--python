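"""Genome-scale windows, component means, metagene profiles and histograms.

All summaries operate on the per-site call table produced by
:mod:`mrrbs.methcall` (chrom, pos, strand, context, meth, unmeth, level).
Site means are pooled: every called site carries equal weight. Read-pooled
methylated/unmethylated totals are carried alongside for count-based tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genome import AnnotationSet, ReferenceSet

COMPONENT_ORDER = ["upstream", "promoter", "exon", "intron", "downstream", "te"]


# ---------------------------------------------------------------------------
# interval helpers


def _merge_intervals(ivs: list[tuple[int, int]]) -> tuple[np.ndarray, np.ndarray]:
    if not ivs:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    ivs = sorted((s, e) for s, e in ivs if e > s)
    starts, ends = [], []
    for s, e in ivs:
        if ends and s <= ends[-1]:
            ends[-1] = max(ends[-1], e)
        else:
            starts.append(s)
            ends.append(e)
    return np.asarray(starts, dtype=np.int64), np.asarray(ends, dtype=np.int64)


def _in_intervals(pos: np.ndarray, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    """Membership of each position in a merged, sorted interval set."""
    if len(starts) == 0 or len(pos) == 0:
        return np.zeros(len(pos), dtype=bool)
    idx = np.searchsorted(starts, pos, side="right") - 1
    ok = idx >= 0
    out = np.zeros(len(pos), dtype=bool)
    out[ok] = pos[ok] < ends[idx[ok]]
    return out


def component_intervals(ann: AnnotationSet, flank: int = 1000, promoter: int = 200,
                        genes: pd.DataFrame | None = None,
                        ) -> dict[str, dict[str, tuple[np.ndarray, np.ndarray]]]:
    """Merged intervals per component type and chromosome (strand-aware).

    ``genes`` restricts the genic components to a subset of gene rows (the
    TE component always reflects the full TE table).
    """
    g = ann.genes if genes is None else genes
    raw: dict[str, dict[str, list[tuple[int, int]]]] = {c: {} for c in COMPONENT_ORDER}

    def add(comp, chrom, s, e):
        raw[comp].setdefault(chrom, []).append((max(s, 0), e))

    for r in g.itertuples(index=False):
        if r.strand == "+":
            add("upstream", r.chrom, r.start - flank, r.start)
            add("promoter", r.chrom, r.start - promoter, r.start)
            add("downstream", r.chrom, r.end, r.end + flank)
        else:
            add("upstream", r.chrom, r.end, r.end + flank)
            add("promoter", r.chrom, r.end, r.end + promoter)
            add("downstream", r.chrom, r.start - flank, r.start)
    gene_ids = set(g["gene_id"])
    for e in ann.exons.itertuples(index=False):
        if e.gene_id in gene_ids:
            add("exon", e.chrom, e.start, e.end)
    introns = ann.introns()
    for i in introns.itertuples(index=False):
        if i.gene_id in gene_ids:
            add("intron", i.chrom, i.start, i.end)
    for t in ann.tes.itertuples(index=False):
        add("te", t.chrom, t.start, t.end)

    return {comp: {chrom: _merge_intervals(ivs) for chrom, ivs in per.items()}
            for comp, per in raw.items()}


def pooled_component_stats(calls: pd.DataFrame,
                           intervals: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]],
                           ) -> pd.DataFrame:
    """Site- and read-pooled methylation per component x context."""
    rows = []
    by_chrom = {chrom: sub for chrom, sub in calls.groupby("chrom")}
    for comp, per in intervals.items():
        picked = []
        for chrom, (starts, ends) in per.items():
            sub = by_chrom.get(chrom)
            if sub is None:
                continue
            mask = _in_intervals(sub["pos"].to_numpy(), starts, ends)
            picked.append(sub.loc[mask])
        if picked:
            sel = pd.concat(picked)
            for ctx, grp in sel.groupby("context"):
                rows.append({
                    "component": comp, "context": ctx,
                    "n_sites": len(grp),
                    "mean_level": float(grp["level"].mean()),
                    "meth_reads": int(grp["meth"].sum()),
                    "unmeth_reads": int(grp["unmeth"].sum()),
                })
    df = pd.DataFrame(rows, columns=["component", "context", "n_sites",
                                     "mean_level", "meth_reads", "unmeth_reads"])
    if len(df):
        df["read_level"] = df["meth_reads"] / (df["meth_reads"] + df["unmeth_reads"])
    else:
        df["read_level"] = pd.Series(dtype=float)
    return df


def component_means(calls: pd.DataFrame, ann: AnnotationSet, flank: int = 1000,
                    promoter: int = 200) -> pd.DataFrame:
    """Pooled-site mean methylation per component x context.

    Components: 1-kb upstream, 200-bp promoter, exon, intron, 1-kb
    downstream (all strand-aware relative to the TSS/TTR) and TE bodies. A
    site inside several genes' components counts once per component type.
    """
    return pooled_component_stats(calls, component_intervals(ann, flank, promoter))


# ---------------------------------------------------------------------------
# windows


def window_profile(calls: pd.DataFrame, ref: ReferenceSet, ann: AnnotationSet,
                   win: int = 200_000, step: int = 100_000) -> pd.DataFrame:
    """Sliding-window mean levels per context plus repeat-base totals."""
    if win < step:
        raise ValueError("window must be >= step")
    contexts = ["CG", "CHG", "CHH"]
    by_chrom = {chrom: sub.sort_values("pos") for chrom, sub in calls.groupby("chrom")}
    rep_by_chrom = {chrom: sub for chrom, sub in ann.repeats.groupby("chrom")}
    rows = []
    for chrom in ref.names():
        L = ref.length(chrom)
        sub = by_chrom.get(chrom)
        reps = rep_by_chrom.get(chrom)
        for start in range(0, max(L, 1), step):
            if start >= L:
                break
            end = min(start + win, L)
            row: dict = {"chrom": chrom, "start": start, "end": end}
            for ctx in contexts:
                if sub is None:
                    row[f"{ctx}_mean"], row[f"{ctx}_sites"] = np.nan, 0
                    continue
                s = sub[sub["context"] == ctx]
                pos = s["pos"].to_numpy()
                lo, hi = np.searchsorted(pos, [start, end])
                lv = s["level"].to_numpy()[lo:hi]
                row[f"{ctx}_mean"] = float(lv.mean()) if len(lv) else np.nan
                row[f"{ctx}_sites"] = int(len(lv))
            rep_bases = 0
            if reps is not None:
                clip = (np.minimum(reps["end"], end) - np.maximum(reps["start"], start))
                rep_bases = int(clip[clip > 0].sum())
            row["repeat_bases"] = rep_bases
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# metagene


def metagene_profile(calls: pd.DataFrame, features: pd.DataFrame, flank: int = 1000,
                     body_bins: int = 10, flank_bin: int = 100,
                     ) -> tuple[pd.DataFrame, int]:
    """Length-normalised feature-body profile with fixed flank bins.

    The body is split into ``body_bins`` equal-length bins (remainder bases
    folded into the last bin); each 1-kb flank into ``flank//flank_bin``
    fixed-width bins. Minus-strand features are mirrored so bin 1 is always
    5'. Features shorter than ``body_bins`` bases are excluded; their count
    is returned alongside the table.
    """
    n_flank_bins = flank // flank_bin
    by_chrom = {chrom: sub.sort_values("pos") for chrom, sub in calls.groupby("chrom")}
    acc: dict[tuple[str, str], list[float]] = {}
    excluded = 0
    for f in features.itertuples(index=False):
        length = f.end - f.start
        if length < body_bins:
            excluded += 1
            continue
        sub = by_chrom.get(f.chrom)
        if sub is None:
            continue
        pos_all = sub["pos"].to_numpy()
        lo, hi = np.searchsorted(pos_all, [f.start - flank, f.end + flank])
        window = sub.iloc[lo:hi]
        pos = window["pos"].to_numpy()
        minus = getattr(f, "strand", "+") == "-"
        # distance from the 5' feature start, negative upstream
        d = (f.end - 1 - pos) if minus else (pos - f.start)
        bin_len = length // body_bins
        labels = np.full(len(pos), -1, dtype=np.int64)
        in_body = (d >= 0) & (d < length)
        labels[in_body] = n_flank_bins + np.minimum(d[in_body] // bin_len,
                                                    body_bins - 1)
        up = d < 0
        up_idx = (-d[up] - 1) // flank_bin  # 0 adjacent to the 5' end
        ok_up = up_idx < n_flank_bins
        labels[np.flatnonzero(up)[ok_up]] = n_flank_bins - 1 - up_idx[ok_up]
        down = d >= length
        dn_idx = (d[down] - length) // flank_bin
        ok_dn = dn_idx < n_flank_bins
        labels[np.flatnonzero(down)[ok_dn]] = (n_flank_bins + body_bins
                                               + dn_idx[ok_dn])
        ctx = window["context"].to_numpy()
        lvl = window["level"].to_numpy()
        for i in np.flatnonzero(labels >= 0):
            acc.setdefault((int(labels[i]), ctx[i]), []).append(float(lvl[i]))

    def bin_name(i: int) -> str:
        if i < n_flank_bins:
            return f"u{i + 1:02d}"
        if i < n_flank_bins + body_bins:
            return f"b{i - n_flank_bins + 1:02d}"
        return f"d{i - n_flank_bins - body_bins + 1:02d}"

    rows = [{"bin_index": i, "bin": bin_name(i), "context": ctx,
             "mean_level": float(np.mean(v)), "n_sites": len(v)}
            for (i, ctx), v in sorted(acc.items())]
    return pd.DataFrame(rows, columns=["bin_index", "bin", "context",
                                       "mean_level", "n_sites"]), excluded


# ---------------------------------------------------------------------------
# histogram


_HIST_LABELS = ["0"] + [f"({10 * i}-{10 * (i + 1)}]" for i in range(10)]


def level_histogram(calls: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-context site counts in an exact-zero bin plus ten 10% bins.

    Returns the histogram (fractions sum to 1 per context) and an
    exact-zero/exact-one accounting table.
    """
    hist_rows, extreme_rows = [], []
    for ctx, grp in calls.groupby("context"):
        lv = grp["level"].to_numpy()
        counts = np.zeros(11, dtype=np.int64)
        counts[0] = int((lv == 0).sum())
        nz = lv[lv > 0]
        # (0,0.1], (0.1,0.2], ..., (0.9,1.0]
        idx = np.ceil(nz * 10 - 1e-12).astype(int)
        counts[1:] = np.bincount(np.clip(idx, 1, 10), minlength=11)[1:]
        n = len(lv)
        for i, label in enumerate(_HIST_LABELS):
            hist_rows.append({"context": ctx, "bin": label,
                              "count": int(counts[i]),
                              "fraction": counts[i] / n if n else 0.0})
        extreme_rows.append({"context": ctx, "n_sites": n,
                             "exact_zero": int((lv == 0).sum()),
                             "exact_one": int((lv == 1).sum())})
    return (pd.DataFrame(hist_rows, columns=["context", "bin", "count", "fraction"]),
            pd.DataFrame(extreme_rows, columns=["context", "n_sites",
                                                "exact_zero", "exact_one"]))
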