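"""In-silico double restriction digestion and size selection.

The reduced representation is built by cutting the genome with two enzymes
(SacI GAGCT^C and MseI T^TAA by default), keeping fragments in a gel
size-selection window (250-500 bp inclusive) and, because the two sticky-end
adaptors are enzyme-specific, requiring one boundary from each enzyme
("mixed ends") for a fragment to amplify. ``capture_stats`` then reports how
many cytosine sites of each context fall inside the sequenced read windows
of the retained fragments.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import AnnotationSet, ReferenceSet

CHROM_END = "end"  # boundary sentinel for chromosome termini


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A restriction enzyme with its top-strand cut offset within the site."""

    name: str
    site: str
    cut_offset: int

    def __post_init__(self) -> None:
        if not re.fullmatch("[ACGT]+", self.site):
            raise ValueError(f"recognition sequence must be over ACGT: {self.site!r}")
        if not 0 <= self.cut_offset <= len(self.site):
            raise ValueError("cut offset outside recognition site")


SACI = RestrictionEnzyme("SacI", "GAGCTC", 5)
MSEI = RestrictionEnzyme("MseI", "TTAA", 1)


@dataclass(frozen=True)
class DigestParams:
    """Size-selection window (inclusive bounds) and the mixed-end rule."""

    min_length: int = 250
    max_length: int = 500
    require_mixed_ends: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.min_length <= self.max_length:
            raise ValueError("need 0 < min_length <= max_length")


@dataclass(frozen=True)
class Fragment:
    chrom: str
    start: int
    end: int
    left_enzyme: str
    right_enzyme: str

    @property
    def length(self) -> int:
        return self.end - self.start


def find_sites(sequence: str, enzyme: RestrictionEnzyme) -> list[int]:
    """Top-strand cut coordinates for every (possibly overlapping) site.

    Sites containing N never match the literal recognition sequence and are
    therefore skipped implicitly.
    """
    pat = re.compile("(?=" + enzyme.site + ")")
    return sorted(m.start() + enzyme.cut_offset for m in pat.finditer(sequence.upper()))


def double_digest(ref: ReferenceSet,
                  enz_a: RestrictionEnzyme = SACI,
                  enz_b: RestrictionEnzyme = MSEI) -> list[Fragment]:
    """Fragment every chromosome at the merged cut list of two enzymes.

    Fragments tile each chromosome exactly; each boundary is labelled with
    the enzyme that produced it (chromosome ends carry the ``end`` sentinel).
    """
    if enz_a.name == enz_b.name:
        raise ValueError("enzymes must be distinct")
    fragments: list[Fragment] = []
    for chrom in ref.names():
        seq = ref[chrom]
        cuts = [(p, enz_a.name) for p in find_sites(seq, enz_a)]
        cuts += [(p, enz_b.name) for p in find_sites(seq, enz_b)]
        cuts.sort()
        merged: list[tuple[int, str]] = []
        for pos, name in cuts:
            if merged and merged[-1][0] == pos:
                continue  # coincident cuts: keep first enzyme's label
            if 0 < pos < len(seq):
                merged.append((pos, name))
        bounds = [(0, CHROM_END)] + merged + [(len(seq), CHROM_END)]
        for (s, left), (e, right) in zip(bounds[:-1], bounds[1:]):
            if e > s:
                fragments.append(Fragment(chrom, s, e, left, right))
    return fragments


def select_representation(fragments: list[Fragment],
                          params: DigestParams = DigestParams()) -> list[Fragment]:
    """Apply gel size selection and (optionally) the mixed-end adaptor rule."""
    out = []
    for f in fragments:
        if not params.min_length <= f.length <= params.max_length:
            continue
        if params.require_mixed_ends:
            ends = {f.left_enzyme, f.right_enzyme}
            if CHROM_END in ends or len(ends) != 2:
                continue
        out.append(f)
    return out


def capture_windows(fragments: list[Fragment], read_len: int = 75) -> dict[str, np.ndarray]:
    """Boolean per-position masks of the sequenced windows of each fragment.

    A fragment contributes its first ``read_len`` bases inward from each end,
    clipped at the fragment middle so short fragments are counted once.
    """
    if read_len <= 0:
        raise ValueError("read_len must be positive")
    spans: dict[str, list[tuple[int, int]]] = {}
    maxend: dict[str, int] = {}
    for f in fragments:
        left = (f.start, min(f.start + read_len, f.end))
        right = (max(f.end - read_len, f.start), f.end)
        spans.setdefault(f.chrom, []).extend([left, right])
        maxend[f.chrom] = max(maxend.get(f.chrom, 0), f.end)
    masks: dict[str, np.ndarray] = {}
    for chrom, ivs in spans.items():
        mask = np.zeros(maxend[chrom], dtype=bool)
        for s, e in ivs:
            mask[s:e] = True
        masks[chrom] = mask
    return masks


def capture_stats(selected: list[Fragment], ref: ReferenceSet, ann: AnnotationSet,
                  read_len: int = 75) -> pd.DataFrame:
    """Per-context capture report of the in-silico reduced representation.

    For each context (CG/CHG/CHH) reports the genomic site total, the number
    and fraction captured inside the read windows, and the split of captured
    sites across genic bodies, TE bodies and other sequence.
    """
    from .methcall import CONTEXT_NAMES, classify_cytosines

    catalog = classify_cytosines(ref)
    masks = capture_windows(selected, read_len) if selected else {}

    region = {}  # chrom -> uint8: 0 other, 1 genic, 2 te (te wins)
    for chrom in ref.names():
        r = np.zeros(ref.length(chrom), dtype=np.uint8)
        for g in ann.genes.itertuples(index=False):
            if g.chrom == chrom:
                r[g.start:g.end] = 1
        for t in ann.tes.itertuples(index=False):
            if t.chrom == chrom:
                r[t.start:t.end] = 2
        region[chrom] = r

    rows = []
    for code, ctx in CONTEXT_NAMES.items():
        total = captured = 0
        reg_counts = np.zeros(3, dtype=np.int64)
        for chrom in ref.names():
            L = ref.length(chrom)
            mask = np.zeros(L, dtype=bool)
            if chrom in masks:
                m = masks[chrom]
                mask[: len(m)] = m
            for strand_arr in (catalog.top[chrom], catalog.bottom[chrom]):
                is_ctx = strand_arr == code
                total += int(is_ctx.sum())
                cap = is_ctx & mask
                captured += int(cap.sum())
                reg_counts += np.bincount(region[chrom][cap], minlength=3)
        frac = captured / total if total else 0.0
        denom = captured if captured else 1
        rows.append({
            "context": ctx,
            "total_sites": total,
            "captured_sites": captured,
            "captured_fraction": frac,
            "captured_genic_fraction": reg_counts[1] / denom,
            "captured_te_fraction": reg_counts[2] / denom,
            "captured_other_fraction": reg_counts[0] / denom,
        })
    return pd.DataFrame(rows)
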