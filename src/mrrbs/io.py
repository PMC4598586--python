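"""Readers and writers for the standard formats the pipeline exchanges.

Coordinates are 0-based half-open internally; BED stays 0-based while
GFF3/SAM/VCF are 1-based on disk. FASTQ may be gzip-compressed (by file
extension).
"""

from __future__ import annotations

import gzip
from pathlib import Path

import pandas as pd
import pysam
from Bio import SeqIO

from .bsalign import AlignmentRecord
from .genome import (EXON_COLUMNS, GENE_COLUMNS, REPEAT_COLUMNS, TE_COLUMNS,
                     AnnotationSet, ReferenceSet)
from .preprocess import ReadPair

# ---------------------------------------------------------------------------
# FASTA


def write_fasta(ref: ReferenceSet, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in ref.names():
            fh.write(f">{name}\n")
            seq = ref[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta(path: str | Path) -> ReferenceSet:
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    return ReferenceSet(seqs)


# ---------------------------------------------------------------------------
# FASTQ


def _open_text(path: str | Path, mode: str):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode + "t")
    return open(path, mode)


def write_fastq_pairs(pairs: list[ReadPair], path1: str | Path,
                      path2: str | Path) -> None:
    with _open_text(path1, "w") as f1, _open_text(path2, "w") as f2:
        for p in pairs:
            f1.write(f"@{p.name}/1\n{p.seq1}\n+\n{p.qual1}\n")
            f2.write(f"@{p.name}/2\n{p.seq2}\n+\n{p.qual2}\n")


def read_fastq_pairs(path1: str | Path, path2: str | Path) -> list[ReadPair]:
    pairs = []
    with _open_text(path1, "r") as f1, _open_text(path2, "r") as f2:
        it1 = SeqIO.parse(f1, "fastq")
        it2 = SeqIO.parse(f2, "fastq")
        for r1, r2 in zip(it1, it2):
            name1 = r1.id.rsplit("/", 1)[0]
            name2 = r2.id.rsplit("/", 1)[0]
            if name1 != name2:
                raise ValueError(f"mate names differ: {r1.id} vs {r2.id}")
            q1 = "".join(chr(q + 33) for q in r1.letter_annotations["phred_quality"])
            q2 = "".join(chr(q + 33) for q in r2.letter_annotations["phred_quality"])
            pairs.append(ReadPair(name1, str(r1.seq), q1, str(r2.seq), q2))
    return pairs


# ---------------------------------------------------------------------------
# GFF3 / BED annotation


def write_annotation_gff3(ann: AnnotationSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in ann.genes.itertuples(index=False):
            attrs = (f"ID={g.gene_id};subgenome={g.subgenome};"
                     f"copy_class={g.copy_class}")
            fh.write(f"{g.chrom}\tmrrbs\tgene\t{g.start + 1}\t{g.end}\t.\t"
                     f"{g.strand}\t.\t{attrs}\n")
        for i, e in enumerate(ann.exons.itertuples(index=False)):
            fh.write(f"{e.chrom}\tmrrbs\texon\t{e.start + 1}\t{e.end}\t.\t"
                     f"{e.strand}\t.\tID={e.gene_id}.exon{i};Parent={e.gene_id}\n")
        for t in ann.tes.itertuples(index=False):
            fh.write(f"{t.chrom}\tmrrbs\ttransposable_element\t{t.start + 1}\t"
                     f"{t.end}\t.\t{t.strand}\t.\tID={t.te_id}\n")


def read_annotation_gff3(path: str | Path,
                         repeats_bed: str | Path | None = None) -> AnnotationSet:
    genes, exons, tes = [], [], []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            chrom, _, ftype, start, end, _, strand, _, attrs = \
                line.rstrip("\n").split("\t")
            fields = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            s, e = int(start) - 1, int(end)
            if ftype == "gene":
                genes.append((fields["ID"], chrom, s, e, strand,
                              fields.get("subgenome"),
                              int(fields["copy_class"]) if "copy_class" in fields
                              else None))
            elif ftype == "exon":
                exons.append((fields["Parent"], chrom, s, e, strand))
            elif ftype == "transposable_element":
                tes.append((fields["ID"], chrom, s, e, strand))
    repeats = read_bed(repeats_bed) if repeats_bed else None
    ann = AnnotationSet(
        genes=pd.DataFrame(genes, columns=GENE_COLUMNS),
        exons=pd.DataFrame(exons, columns=EXON_COLUMNS),
        tes=pd.DataFrame(tes, columns=TE_COLUMNS),
    )
    if repeats is not None:
        rep = repeats.rename(columns={"name": "repeat_id"})
        rep["kind"] = rep["repeat_id"].str.startswith("ta").map(
            {True: "tandem", False: "inverted"})
        ann.repeats = rep[REPEAT_COLUMNS]
    return ann


def write_bed(df: pd.DataFrame, path: str | Path, name_col: str,
              strand_col: str | None = None) -> None:
    """BED6 from a DataFrame with chrom/start/end plus a name column."""
    with open(path, "w") as fh:
        for r in df.itertuples(index=False):
            strand = getattr(r, strand_col) if strand_col else "."
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{getattr(r, name_col)}\t0\t"
                     f"{strand}\n")


def read_bed(path: str | Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            rows.append((f[0], int(f[1]), int(f[2]),
                         f[3] if len(f) > 3 else ".",
                         f[5] if len(f) > 5 else "."))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "strand"])


def write_fragments_bed(fragments, path: str | Path) -> None:
    with open(path, "w") as fh:
        for f in fragments:
            fh.write(f"{f.chrom}\t{f.start}\t{f.end}\t"
                     f"{f.left_enzyme}_{f.right_enzyme}\t0\t.\n")


# ---------------------------------------------------------------------------
# TSV tables and bedGraph


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_bedgraph(calls: pd.DataFrame, path: str | Path,
                   context: str | None = None) -> None:
    sub = calls if context is None else calls[calls["context"] == context]
    with open(path, "w") as fh:
        for r in sub.itertuples(index=False):
            fh.write(f"{r.chrom}\t{r.pos}\t{r.pos + 1}\t{r.level:.4f}\n")


# ---------------------------------------------------------------------------
# VCF


def write_vcf(variants: pd.DataFrame, ref: ReferenceSet, path: str | Path) -> None:
    header = pysam.VariantHeader()
    for name in ref.names():
        header.contigs.add(name, length=ref.length(name))
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for r in variants.sort_values(["chrom", "pos"]).itertuples(index=False):
            rec = vf.new_record(contig=r.chrom, start=int(r.pos),
                                stop=int(r.pos) + 1, alleles=(r.ref, r.alt))
            vf.write(rec)


def read_vcf(path: str | Path) -> pd.DataFrame:
    rows = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            rows.append((rec.contig, rec.start, rec.ref, rec.alts[0]))
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])


# ---------------------------------------------------------------------------
# SAM


def write_sam(records: list[AlignmentRecord], ref: ReferenceSet,
              path: str | Path) -> None:
    """Paired SAM with XB (bisulfite strand), XG (alphabet) and NM tags."""
    header = {"HD": {"VN": "1.6", "SO": "unsorted"},
              "SQ": [{"SN": n, "LN": ref.length(n)} for n in ref.names()]}
    tid = {n: i for i, n in enumerate(ref.names())}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rec in records:
            for mate, (pos, seq, qual) in enumerate(
                    [(rec.pos1, rec.seq1_oriented, rec.qual1_oriented),
                     (rec.pos2, rec.seq2_oriented, rec.qual2_oriented)]):
                a = pysam.AlignedSegment()
                a.query_name = rec.name
                a.reference_id = tid[rec.chrom]
                a.reference_start = pos
                mate_strand = rec.r1_strand if mate == 1 else (
                    "-" if rec.r1_strand == "+" else "+")
                own_strand = rec.r1_strand if mate == 0 else (
                    "-" if rec.r1_strand == "+" else "+")
                flag = 0x1 | 0x2 | (0x40 if mate == 0 else 0x80)
                if own_strand == "-":
                    flag |= 0x10
                if mate_strand == "-":
                    flag |= 0x20
                a.flag = flag
                a.mapping_quality = 42
                a.cigarstring = f"{len(seq)}M"
                a.query_sequence = seq
                a.query_qualities = pysam.qualitystring_to_array(qual)
                a.next_reference_id = tid[rec.chrom]
                a.next_reference_start = rec.pos2 if mate == 0 else rec.pos1
                a.set_tag("XB", rec.bs_strand)
                a.set_tag("XG", rec.conversion)
                a.set_tag("NM", rec.mismatches)
                out.write(a)


def read_sam(path: str | Path) -> list[AlignmentRecord]:
    by_name: dict[str, dict[int, pysam.AlignedSegment]] = {}
    records = []
    with pysam.AlignmentFile(str(path), "r") as fh:
        for a in fh:
            slot = by_name.setdefault(a.query_name, {})
            slot[0 if a.is_read1 else 1] = a
            if len(slot) == 2:
                r1, r2 = slot[0], slot[1]
                records.append(AlignmentRecord(
                    name=a.query_name, chrom=r1.reference_name,
                    pos1=r1.reference_start, pos2=r2.reference_start,
                    r1_strand="-" if r1.is_reverse else "+",
                    bs_strand=r1.get_tag("XB"), conversion=r1.get_tag("XG"),
                    mismatches=int(r1.get_tag("NM")),
                    seq1_oriented=r1.query_sequence,
                    qual1_oriented=pysam.qualities_to_qualitystring(
                        r1.query_qualities),
                    seq2_oriented=r2.query_sequence,
                    qual2_oriented=pysam.qualities_to_qualitystring(
                        r2.query_qualities),
                ))
                del by_name[a.query_name]
    return records
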