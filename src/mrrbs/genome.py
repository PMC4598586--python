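"""Reference genome and annotation containers.

A :class:`ReferenceSet` is an ordered mapping of chromosome name to sequence;
an :class:`AnnotationSet` bundles gene models (with subgenome and copy-number
labels), transposable-element intervals and tandem/inverted repeat tracks as
pandas DataFrames. All coordinates are 0-based half-open on the top strand;
1-based coordinates appear only in emitted GFF3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _seq

GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "strand", "subgenome", "copy_class"]
EXON_COLUMNS = ["gene_id", "chrom", "start", "end", "strand"]
TE_COLUMNS = ["te_id", "chrom", "start", "end", "strand"]
REPEAT_COLUMNS = ["repeat_id", "chrom", "start", "end", "kind"]

SUBGENOMES = ("LF", "MF1", "MF2")
COPY_CLASSES = (1, 2, 3)


def _empty(columns: list[str]) -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=object) for c in columns})


@dataclass
class ReferenceSet:
    """Ordered chromosome name -> sequence mapping with cached code arrays."""

    sequences: dict[str, str]
    _encoded: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def names(self) -> list[str]:
        return list(self.sequences)

    def __getitem__(self, name: str) -> str:
        return self.sequences[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sequences

    def length(self, name: str) -> int:
        return len(self.sequences[name])

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def encoded(self, name: str) -> np.ndarray:
        """uint8 code array for a chromosome (cached)."""
        arr = self._encoded.get(name)
        if arr is None:
            arr = _seq.encode(self.sequences[name])
            self._encoded[name] = arr
        return arr


@dataclass
class AnnotationSet:
    """Gene/TE/repeat annotation tables sharing a coordinate system.

    genes:   gene_id, chrom, start, end, strand, subgenome (LF/MF1/MF2),
             copy_class (1/2/3)
    exons:   gene_id, chrom, start, end, strand
    tes:     te_id, chrom, start, end, strand
    repeats: repeat_id, chrom, start, end, kind (tandem/inverted)
    """

    genes: pd.DataFrame = field(default_factory=lambda: _empty(GENE_COLUMNS))
    exons: pd.DataFrame = field(default_factory=lambda: _empty(EXON_COLUMNS))
    tes: pd.DataFrame = field(default_factory=lambda: _empty(TE_COLUMNS))
    repeats: pd.DataFrame = field(default_factory=lambda: _empty(REPEAT_COLUMNS))

    def introns(self) -> pd.DataFrame:
        """Derive intron intervals (gene body minus exons), strand-aware labels."""
        rows = []
        if len(self.exons) == 0:
            return _empty(EXON_COLUMNS)
        exons_by_gene = self.exons.groupby("gene_id")
        for gene in self.genes.itertuples(index=False):
            try:
                ex = exons_by_gene.get_group(gene.gene_id)
            except KeyError:
                continue
            ex = ex.sort_values("start")
            prev_end = None
            for e in ex.itertuples(index=False):
                if prev_end is not None and e.start > prev_end:
                    rows.append((gene.gene_id, gene.chrom, prev_end, e.start, gene.strand))
                prev_end = e.end
        return pd.DataFrame(rows, columns=EXON_COLUMNS) if rows else _empty(EXON_COLUMNS)

    def validate(self, ref: ReferenceSet | None = None) -> None:
        """Check structural invariants; raises ValueError on violation."""
        for name, df in (("genes", self.genes), ("exons", self.exons),
                         ("tes", self.tes), ("repeats", self.repeats)):
            if len(df) and not (df["start"] < df["end"]).all():
                raise ValueError(f"{name}: empty or inverted interval")
        if ref is not None:
            for name, df in (("genes", self.genes), ("tes", self.tes), ("repeats", self.repeats)):
                for r in df.itertuples(index=False):
                    if r.chrom not in ref or r.end > ref.length(r.chrom) or r.start < 0:
                        raise ValueError(f"{name}: {r} outside chromosome bounds")
        # genes must not overlap one another
        for chrom, sub in self.genes.groupby("chrom"):
            s = sub.sort_values("start")
            if (s["start"].values[1:] < s["end"].values[:-1]).any():
                raise ValueError(f"overlapping genes on {chrom}")
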