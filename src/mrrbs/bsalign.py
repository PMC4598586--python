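"""Non-directional three-letter bisulfite paired alignment.

A non-directional bisulfite library yields four strands per fragment: the
converted original top (OT) and bottom (OB) strands and their PCR
complements (CTOT, CTOB). Alignment therefore evaluates four hypotheses,
matching the C->T converted read against the C->T converted reference (OT,
CTOT) or the G->A converted read against the G->A reference (OB, CTOB), in
the orientation each hypothesis implies. Because both read and reference
are collapsed to the same three-letter alphabet, a retained (methylated) C
in the read is never charged as a mismatch.

The search is exact-seed (k-mer, default k=20) plus full verification of
both mates with a total substitution budget per pair; only pairs with a
strictly unique best-scoring location are reported, mirroring a
uniquely-mapped-reads filter. A ``raw``-alphabet two-hypothesis mode serves
the non-bisulfite (ddRAD) reads.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import _seq
from .genome import ReferenceSet
from .preprocess import ReadPair

BS_HYPOTHESES = (  # (alphabet, mate1 genomic strand, bisulfite strand label)
    ("CT", "+", "OT"),
    ("CT", "-", "CTOT"),
    ("GA", "-", "OB"),
    ("GA", "+", "CTOB"),
)
PLAIN_HYPOTHESES = (
    ("raw", "+", "fwd"),
    ("raw", "-", "rev"),
)

_CONVERTERS = {
    "raw": lambda a: a,
    "CT": _seq.convert_ct,
    "GA": _seq.convert_ga,
}


def _kmer_codes(arr: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Polynomial 2-bit codes of all k-mers plus a validity mask (no N)."""
    n = len(arr) - k + 1
    codes = np.zeros(n, dtype=np.uint64)
    valid = np.ones(n, dtype=bool)
    for j in range(k):
        b = arr[j:j + n]
        codes = codes * np.uint64(4) + (b & np.uint8(3)).astype(np.uint64)
        valid &= b != _seq.N
    return codes, valid


def _encode_kmer(arr: np.ndarray) -> np.uint64 | None:
    if (arr == _seq.N).any():
        return None
    code = 0
    for b in arr:
        code = code * 4 + int(b & 3)
    return np.uint64(code)


@dataclass
class ConvertedIndex:
    """Exact-match k-mer index over the raw and bisulfite-converted alphabets."""

    ref: ReferenceSet
    k: int
    chroms: list[str]
    genomes: dict[str, dict[str, np.ndarray]]          # alphabet -> chrom -> codes
    tables: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]]  # sorted (codes, pos)

    def lookup(self, alphabet: str, kmer: str | np.ndarray) -> list[tuple[str, int]]:
        """All genome positions whose converted k-mer equals the query."""
        arr = _seq.encode(kmer) if isinstance(kmer, str) else kmer
        if len(arr) != self.k:
            raise ValueError(f"query length {len(arr)} != k={self.k}")
        code = _encode_kmer(arr)
        if code is None:
            return []
        out = []
        for chrom in self.chroms:
            codes, pos = self.tables[alphabet][chrom]
            lo = np.searchsorted(codes, code, "left")
            hi = np.searchsorted(codes, code, "right")
            out.extend((chrom, int(p)) for p in pos[lo:hi])
        return out


def build_bs_index(ref: ReferenceSet, k: int = 20) -> ConvertedIndex:
    """Index a reference over the raw, C->T and G->A alphabets."""
    if k < 10:
        raise ValueError("k must be >= 10")
    chroms = []
    for chrom in ref.names():
        if ref.length(chrom) < k:
            warnings.warn(f"chromosome {chrom} shorter than k={k}; excluded from index")
        else:
            chroms.append(chrom)
    genomes: dict[str, dict[str, np.ndarray]] = {}
    tables: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = {}
    for alphabet, conv in _CONVERTERS.items():
        genomes[alphabet] = {}
        tables[alphabet] = {}
        for chrom in chroms:
            g = conv(ref.encoded(chrom))
            genomes[alphabet][chrom] = g
            codes, valid = _kmer_codes(g, k)
            pos = np.flatnonzero(valid).astype(np.int64)
            codes = codes[pos]
            order = np.argsort(codes, kind="stable")
            tables[alphabet][chrom] = (codes[order], pos[order])
    return ConvertedIndex(ref=ref, k=k, chroms=chroms, genomes=genomes, tables=tables)


@dataclass
class AlignmentRecord:
    """A uniquely-placed read pair with strand bookkeeping for calling.

    ``seqN_oriented``/``qualN_oriented`` hold the original (unconverted)
    mate bases written in top-strand orientation, so downstream pileup can
    read methylation evidence directly against reference coordinates.
    """

    name: str
    chrom: str
    pos1: int
    pos2: int
    r1_strand: str
    bs_strand: str
    conversion: str
    mismatches: int
    seq1_oriented: str
    qual1_oriented: str
    seq2_oriented: str
    qual2_oriented: str
    unique: bool = True

    @property
    def span(self) -> tuple[int, int]:
        s = min(self.pos1, self.pos2)
        e = max(self.pos1 + len(self.seq1_oriented), self.pos2 + len(self.seq2_oriented))
        return s, e


def _mismatches_at(garr: np.ndarray, pos: int, read: np.ndarray) -> int | None:
    if pos < 0 or pos + len(read) > len(garr):
        return None
    return int(np.count_nonzero(garr[pos:pos + len(read)] != read))


def _scan_window(garr: np.ndarray, lo: int, hi: int, read: np.ndarray,
                 budget: int) -> list[tuple[int, int]]:
    """Mismatch counts of ``read`` at every start in [lo, hi] within budget."""
    lo = max(lo, 0)
    hi = min(hi, len(garr) - len(read))
    if hi < lo:
        return []
    seg = garr[lo: hi + len(read)]
    view = np.lib.stride_tricks.sliding_window_view(seg, len(read))
    mm = np.count_nonzero(view != read, axis=1)
    ok = np.flatnonzero(mm <= budget)
    return [(lo + int(i), int(mm[i])) for i in ok]


def _seed_offsets(read_len: int, k: int) -> list[int]:
    offs = list(range(0, max(read_len - k + 1, 1), k))
    last = read_len - k
    if last > 0 and last not in offs:
        offs.append(last)
    return offs


def _candidates_for_hypothesis(oriented1: np.ndarray, oriented2: np.ndarray,
                               conv: str, r1_strand: str, index: ConvertedIndex,
                               max_mm: int, max_span: int,
                               ) -> list[tuple[str, int, int, int]]:
    """Candidate (chrom, pos1, pos2, mismatches) tuples for one hypothesis."""
    convert = _CONVERTERS[conv]
    c1, c2 = convert(oriented1), convert(oriented2)
    left, right = (c1, c2) if r1_strand == "+" else (c2, c1)
    n_left, n_right = len(left), len(right)
    results: dict[tuple[str, int, int], int] = {}

    def note(chrom: str, p_left: int, p_right: int, mm: int) -> None:
        if p_right < p_left or p_right + n_right - p_left > max_span:
            return
        key = (chrom, p_left, p_right)
        if key not in results or mm < results[key]:
            results[key] = mm

    k = index.k
    # Seed from the left mate and scan the right mate inside the insert
    # window. With >= max_mm+1 disjoint seeds in the anchor, a within-budget
    # candidate always keeps one exact seed, so the mirrored pass (anchor on
    # the right mate) is only needed for short anchors.
    passes = [(left, right, True)]
    if n_left < (max_mm + 1) * k:
        passes.append((right, left, False))
    for anchor, other, anchor_is_left in passes:
        n_anchor = len(anchor)
        if n_anchor < k:
            continue
        seen_anchor: set[tuple[str, int]] = set()
        for off in _seed_offsets(n_anchor, k):
            code = _encode_kmer(anchor[off:off + k])
            if code is None:
                continue
            for chrom in index.chroms:
                codes, pos = index.tables[conv][chrom]
                lo = np.searchsorted(codes, code, "left")
                hi = np.searchsorted(codes, code, "right")
                garr = index.genomes[conv][chrom]
                for hit in pos[lo:hi]:
                    p_anchor = int(hit) - off
                    if (chrom, p_anchor) in seen_anchor:
                        continue
                    seen_anchor.add((chrom, p_anchor))
                    mm_a = _mismatches_at(garr, p_anchor, anchor)
                    if mm_a is None or mm_a > max_mm:
                        continue
                    if anchor_is_left:
                        w_lo = p_anchor
                        w_hi = p_anchor + max_span - len(other)
                    else:
                        w_lo = p_anchor + n_anchor - max_span
                        w_hi = p_anchor
                    for p_other, mm_o in _scan_window(garr, w_lo, w_hi, other,
                                                      max_mm - mm_a):
                        if anchor_is_left:
                            note(chrom, p_anchor, p_other, mm_a + mm_o)
                        else:
                            note(chrom, p_other, p_anchor, mm_a + mm_o)
    if r1_strand == "+":
        return [(c, pl, pr, mm) for (c, pl, pr), mm in results.items()]
    return [(c, pr, pl, mm) for (c, pl, pr), mm in results.items()]


def _orient_pair(pair: ReadPair, r1_strand: str,
                 ) -> tuple[np.ndarray, np.ndarray, str, str, str, str]:
    s1, q1 = pair.seq1, pair.qual1
    s2, q2 = pair.seq2, pair.qual2
    if r1_strand == "+":
        o1, oq1 = s1, q1
        o2, oq2 = _seq.revcomp(s2), q2[::-1]
    else:
        o1, oq1 = _seq.revcomp(s1), q1[::-1]
        o2, oq2 = s2, q2
    return _seq.encode(o1), _seq.encode(o2), o1, oq1, o2, oq2


def _align(pair: ReadPair, index: ConvertedIndex, hypotheses, max_mm: int,
           max_span: int) -> AlignmentRecord | None:
    all_cands: dict[tuple[str, int, int], tuple[int, tuple]] = {}
    oriented_cache = {}
    for conv, r1s, label in hypotheses:
        if r1s not in oriented_cache:
            oriented_cache[r1s] = _orient_pair(pair, r1s)
        o1, o2, s1, q1, s2, q2 = oriented_cache[r1s]
        for chrom, p1, p2, mm in _candidates_for_hypothesis(
                o1, o2, conv, r1s, index, max_mm, max_span):
            key = (chrom, p1, p2)
            if key not in all_cands or mm < all_cands[key][0]:
                all_cands[key] = (mm, (conv, r1s, label, s1, q1, s2, q2))
    if not all_cands:
        return None
    best = min(mm for mm, _ in all_cands.values())
    winners = [(key, meta) for key, (mm, meta) in all_cands.items() if mm == best]
    if len(winners) != 1:
        return None  # ambiguous
    (chrom, p1, p2), (conv, r1s, label, s1, q1, s2, q2) = winners[0]
    return AlignmentRecord(
        name=pair.name, chrom=chrom, pos1=p1, pos2=p2, r1_strand=r1s,
        bs_strand=label, conversion=conv, mismatches=best,
        seq1_oriented=s1, qual1_oriented=q1, seq2_oriented=s2, qual2_oriented=q2,
    )


def align_bs_pair(pair: ReadPair, index: ConvertedIndex, max_mm: int = 1,
                  max_span: int = 520) -> AlignmentRecord | None:
    """Align one bisulfite pair under all four strand hypotheses.

    Returns the strictly unique best candidate, or None when the pair is
    unaligned or ambiguous (these are outcomes, not errors).
    """
    return _align(pair, index, BS_HYPOTHESES, max_mm, max_span)


def align_plain_pair(pair: ReadPair, index: ConvertedIndex, max_mm: int = 1,
                     max_span: int = 520) -> AlignmentRecord | None:
    """Align one non-bisulfite (ddRAD) pair on the raw alphabet."""
    return _align(pair, index, PLAIN_HYPOTHESES, max_mm, max_span)


def align_reads(pairs, index: ConvertedIndex, mode: str = "bisulfite",
                max_mm: int = 1, max_span: int = 520,
                ) -> tuple[list[AlignmentRecord], dict[str, int]]:
    """Batch alignment; returns records plus aligned/unplaced tallies."""
    fn = align_bs_pair if mode == "bisulfite" else align_plain_pair
    records = []
    stats = {"input_pairs": 0, "aligned": 0, "unplaced": 0}
    for pair in pairs:
        stats["input_pairs"] += 1
        rec = fn(pair, index, max_mm=max_mm, max_span=max_span)
        if rec is None:
            stats["unplaced"] += 1
        else:
            stats["aligned"] += 1
            records.append(rec)
    return records, stats
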