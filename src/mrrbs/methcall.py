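"""Cytosine context classification, pileup, methylation and SNP calling.

Context is always determined from the reference genome, never from the
(bisulfite-converted) reads: a cytosine followed by G is CG; else if the
next-next base is G it is CHG; otherwise CHH (H = A, C or T). Sites whose
context cannot be resolved (chromosome edge or flanking N) are excluded.

Methylation calls count read bases at catalogued cytosines: on the
original-top bisulfite strands a C is methylated and a T unmethylated; on
the original-bottom strands the informative bases, in top-strand
coordinates, are G (methylated) and A (unmethylated). Bases below the
quality floor are skipped, and where mates of a pair overlap each genomic
position contributes once (read 1 wins).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _seq
from .bsalign import AlignmentRecord
from .genome import ReferenceSet

CONTEXT_NONE, CONTEXT_CG, CONTEXT_CHG, CONTEXT_CHH = 0, 1, 2, 3
CONTEXT_NAMES = {CONTEXT_CG: "CG", CONTEXT_CHG: "CHG", CONTEXT_CHH: "CHH"}
CONTEXT_CODES = {v: k for k, v in CONTEXT_NAMES.items()}


@dataclass
class ContextCatalog:
    """Dense per-position context codes for both strands of every chromosome."""

    top: dict[str, np.ndarray]
    bottom: dict[str, np.ndarray]

    def counts(self) -> dict[str, int]:
        out = {name: 0 for name in CONTEXT_NAMES.values()}
        for arrs in (self.top, self.bottom):
            for arr in arrs.values():
                bc = np.bincount(arr, minlength=4)
                for code, name in CONTEXT_NAMES.items():
                    out[name] += int(bc[code])
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for strand, arrs in (("+", self.top), ("-", self.bottom)):
            for chrom, arr in arrs.items():
                pos = np.flatnonzero(arr)
                for p in pos:
                    rows.append((chrom, int(p), strand, CONTEXT_NAMES[arr[p]]))
        df = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "context"])
        return df.sort_values(["chrom", "pos", "strand"]).reset_index(drop=True)


def classify_cytosines(ref: ReferenceSet) -> ContextCatalog:
    """Scan both strands of the reference and classify every cytosine."""
    top: dict[str, np.ndarray] = {}
    bottom: dict[str, np.ndarray] = {}
    for chrom in ref.names():
        arr = ref.encoded(chrom)
        L = len(arr)
        t = np.zeros(L, dtype=np.uint8)
        b = np.zeros(L, dtype=np.uint8)
        if L == 0:
            top[chrom], bottom[chrom] = t, b
            continue
        n1 = np.full(L, _seq.N, dtype=np.uint8)  # base at p+1
        n2 = np.full(L, _seq.N, dtype=np.uint8)  # base at p+2
        n1[:-1] = arr[1:]
        if L >= 2:
            n2[:-2] = arr[2:]
        is_c = arr == _seq.C
        h1 = (n1 == _seq.A) | (n1 == _seq.C) | (n1 == _seq.T)
        h2 = (n2 == _seq.A) | (n2 == _seq.C) | (n2 == _seq.T)
        t[is_c & (n1 == _seq.G)] = CONTEXT_CG
        t[is_c & h1 & (n2 == _seq.G)] = CONTEXT_CHG
        t[is_c & h1 & h2] = CONTEXT_CHH
        # bottom strand: C at top-G positions, reading 5'->3' towards lower coords
        p1 = np.full(L, _seq.N, dtype=np.uint8)  # base at p-1
        p2 = np.full(L, _seq.N, dtype=np.uint8)  # base at p-2
        p1[1:] = arr[:-1]
        if L >= 2:
            p2[2:] = arr[:-2]
        is_g = arr == _seq.G
        # complements: next base on bottom strand is complement(top[p-1])
        g1 = (p1 == _seq.T) | (p1 == _seq.G) | (p1 == _seq.A)  # H on bottom
        g2 = (p2 == _seq.T) | (p2 == _seq.G) | (p2 == _seq.A)
        b[is_g & (p1 == _seq.C)] = CONTEXT_CG
        b[is_g & g1 & (p2 == _seq.C)] = CONTEXT_CHG
        b[is_g & g1 & g2] = CONTEXT_CHH
        top[chrom], bottom[chrom] = t, b
    return ContextCatalog(top=top, bottom=bottom)


@dataclass
class PileupCounts:
    """Raw methylated/unmethylated counts per strand and position."""

    meth_top: dict[str, np.ndarray]
    unmeth_top: dict[str, np.ndarray]
    meth_bottom: dict[str, np.ndarray]
    unmeth_bottom: dict[str, np.ndarray]


def _pair_consensus(rec: AlignmentRecord) -> tuple[int, np.ndarray, np.ndarray]:
    """Merge the two mates of a pair into one top-strand base/quality buffer.

    Overlapping genomic positions take mate 1's base so each position is
    counted at most once per pair.
    """
    s1, q1 = _seq.encode(rec.seq1_oriented), _seq.phred_to_array(rec.qual1_oriented)
    s2, q2 = _seq.encode(rec.seq2_oriented), _seq.phred_to_array(rec.qual2_oriented)
    start = min(rec.pos1, rec.pos2)
    end = max(rec.pos1 + len(s1), rec.pos2 + len(s2))
    base = np.full(end - start, 255, dtype=np.uint8)
    qual = np.full(end - start, -1, dtype=np.int16)
    base[rec.pos2 - start: rec.pos2 - start + len(s2)] = s2
    qual[rec.pos2 - start: rec.pos2 - start + len(s2)] = q2
    base[rec.pos1 - start: rec.pos1 - start + len(s1)] = s1
    qual[rec.pos1 - start: rec.pos1 - start + len(s1)] = q1
    return start, base, qual


def pileup(alignments: list[AlignmentRecord], catalog: ContextCatalog,
           ref: ReferenceSet, min_baseq: int = 20) -> PileupCounts:
    """Accumulate methylated/unmethylated evidence at catalogued cytosines."""
    shape = {c: np.zeros(ref.length(c), dtype=np.uint32) for c in ref.names()}
    counts = PileupCounts(
        meth_top={c: a.copy() for c, a in shape.items()},
        unmeth_top={c: a.copy() for c, a in shape.items()},
        meth_bottom={c: a.copy() for c, a in shape.items()},
        unmeth_bottom={c: a.copy() for c, a in shape.items()},
    )
    for rec in alignments:
        if rec.chrom not in catalog.top:
            raise KeyError(f"alignment on unknown chromosome {rec.chrom!r}")
        start, base, qual = _pair_consensus(rec)
        span = slice(start, start + len(base))
        ok = qual >= min_baseq
        if rec.conversion == "CT":  # OT/CTOT: top-strand cytosines
            sites = catalog.top[rec.chrom][span] != CONTEXT_NONE
            meth = sites & ok & (base == _seq.C)
            unmeth = sites & ok & (base == _seq.T)
            np.add.at(counts.meth_top[rec.chrom], start + np.flatnonzero(meth), 1)
            np.add.at(counts.unmeth_top[rec.chrom], start + np.flatnonzero(unmeth), 1)
        else:  # GA: OB/CTOB: bottom-strand cytosines, top coordinates
            sites = catalog.bottom[rec.chrom][span] != CONTEXT_NONE
            meth = sites & ok & (base == _seq.G)
            unmeth = sites & ok & (base == _seq.A)
            np.add.at(counts.meth_bottom[rec.chrom], start + np.flatnonzero(meth), 1)
            np.add.at(counts.unmeth_bottom[rec.chrom], start + np.flatnonzero(unmeth), 1)
    return counts


def call_levels(counts: PileupCounts, catalog: ContextCatalog,
                min_depth: int = 10) -> pd.DataFrame:
    """Emit per-site calls (chrom, pos, strand, context, meth, unmeth, level)
    for sites reaching the depth floor."""
    frames = []
    for strand, meth_d, unmeth_d, ctx_d in (
        ("+", counts.meth_top, counts.unmeth_top, catalog.top),
        ("-", counts.meth_bottom, counts.unmeth_bottom, catalog.bottom),
    ):
        for chrom, ctx in ctx_d.items():
            m = meth_d[chrom]
            u = unmeth_d[chrom]
            cov = m.astype(np.int64) + u
            keep = (cov >= min_depth) & (ctx != CONTEXT_NONE)
            pos = np.flatnonzero(keep)
            if len(pos) == 0:
                continue
            frames.append(pd.DataFrame({
                "chrom": chrom,
                "pos": pos,
                "strand": strand,
                "context": pd.Series(ctx[pos]).map(CONTEXT_NAMES),
                "meth": m[pos].astype(np.int64),
                "unmeth": u[pos].astype(np.int64),
            }))
    if not frames:
        return pd.DataFrame(columns=["chrom", "pos", "strand", "context",
                                     "meth", "unmeth", "level"])
    calls = pd.concat(frames, ignore_index=True)
    calls["level"] = calls["meth"] / (calls["meth"] + calls["unmeth"])
    return calls.sort_values(["chrom", "pos", "strand"]).reset_index(drop=True)


def call_snps(alignments: list[AlignmentRecord], ref: ReferenceSet,
              min_baseq: int = 20, min_alt_count: int = 1) -> pd.DataFrame:
    """Permissive SNP calling from plain (non-bisulfite) paired alignments.

    A position is a candidate when at least ``min_alt_count`` bases of
    quality >= ``min_baseq`` differ from the reference; the majority
    alternate allele is reported. Deliberately permissive: candidates are
    used to mask methylation sites, so false positives only cost sites.
    """
    base_counts = {c: np.zeros((4, ref.length(c)), dtype=np.uint32) for c in ref.names()}
    for rec in alignments:
        if rec.chrom not in base_counts:
            raise KeyError(f"alignment on unknown chromosome {rec.chrom!r}")
        start, base, qual = _pair_consensus(rec)
        ok = (qual >= min_baseq) & (base < 4)
        idx = np.flatnonzero(ok)
        np.add.at(base_counts[rec.chrom], (base[idx], start + idx), 1)
    rows = []
    for chrom in ref.names():
        bc = base_counts[chrom]
        refarr = ref.encoded(chrom)
        total = bc.sum(axis=0)
        covered = np.flatnonzero(total)
        for p in covered:
            r = refarr[p]
            col = bc[:, p].copy()
            if r < 4:
                col[r] = 0
            alt_total = int(col.sum())
            if alt_total >= min_alt_count:
                alt = int(col.argmax())
                rows.append((chrom, int(p), _seq.decode(np.array([r], np.uint8)),
                             _seq.decode(np.array([alt], np.uint8))))
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])


def mask_sites(calls: pd.DataFrame, variants: pd.DataFrame,
               ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop calls whose context-defining motif overlaps a candidate SNP.

    The motif window is strand-oriented: C..C+1 for CG and C..C+2 for
    CHG/CHH on the plus strand, mirrored on the minus strand. Returns the
    retained calls and the removed-site count per context.
    """
    removed = {name: 0 for name in CONTEXT_NAMES.values()}
    if len(calls) == 0 or variants is None or len(variants) == 0:
        return calls.copy(), removed
    var_pos = {chrom: np.sort(sub["pos"].to_numpy())
               for chrom, sub in variants.groupby("chrom")}
    width = calls["context"].map({"CG": 1, "CHG": 2, "CHH": 2}).to_numpy()
    sign = np.where(calls["strand"].to_numpy() == "+", 1, -1)
    pos = calls["pos"].to_numpy()
    hit = np.zeros(len(calls), dtype=bool)
    for chrom, vp in var_pos.items():
        in_chrom = (calls["chrom"] == chrom).to_numpy()
        for off in range(3):
            active = in_chrom & (width >= off)
            q = pos[active] + sign[active] * off
            idx = np.searchsorted(vp, q)
            found = (idx < len(vp)) & (vp[np.minimum(idx, len(vp) - 1)] == q)
            hit[np.flatnonzero(active)[found]] = True
    for name in removed:
        removed[name] = int((hit & (calls["context"] == name).to_numpy()).sum())
    return calls.loc[~hit].reset_index(drop=True), removed
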