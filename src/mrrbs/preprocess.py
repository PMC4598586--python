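"""Read trimming and quality filtering.

Raw pairs are trimmed by stripping the residual enzyme recognition sequence
from the 5' end of each mate when present (including its deterministic
bisulfite-converted forms) and keeping the first 75 bases. Pairs in which
either mate has strictly more than 5% of bases below Phred 30 are dropped;
the filter acts on whole pairs because downstream alignment is paired.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

from . import _seq


@dataclass(frozen=True)
class ReadPair:
    """A paired-end record: mate bases plus Phred+33 quality strings."""

    name: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str

    def __post_init__(self) -> None:
        if len(self.seq1) != len(self.qual1) or len(self.seq2) != len(self.qual2):
            raise ValueError(f"{self.name}: bases and qualities differ in length")


def _converted_forms(residue: str) -> set[str]:
    """All deterministic bisulfite images of a residue: each C may read T
    (converted strand) or each G may read A (complementary strand)."""
    forms = set()
    for which in ("C", "T"), ("G", "A"):
        options = [(b,) if b != which[0] else which for b in residue]
        forms.update("".join(c) for c in product(*options))
    return forms


def default_residues(sites: tuple[str, ...] = ("AGCTC", "TAA")) -> list[str]:
    """Expected 5' residual sequences (SacI and MseI ligation scars) plus
    their bisulfite-converted variants, longest first."""
    forms: set[str] = set()
    for s in sites:
        forms |= _converted_forms(s)
    return sorted(forms, key=len, reverse=True)


_DEFAULT_RESIDUES = default_residues()


def _trim_one(seq: str, qual: str, residues: list[str], keep_len: int) -> tuple[str, str]:
    # residue stripping only applies to raw (untrimmed) reads, which keeps
    # the operation idempotent: a read already at keep_len is left alone.
    if len(seq) > keep_len:
        for res in residues:
            if seq.startswith(res):
                seq, qual = seq[len(res):], qual[len(res):]
                break
    return seq[:keep_len], qual[:keep_len]


def trim_pair(pair: ReadPair, residues: list[str] | None = None,
              keep_len: int = 75) -> ReadPair:
    """Strip 5' enzyme residues and truncate both mates to ``keep_len``."""
    residues = _DEFAULT_RESIDUES if residues is None else residues
    s1, q1 = _trim_one(pair.seq1, pair.qual1, residues, keep_len)
    s2, q2 = _trim_one(pair.seq2, pair.qual2, residues, keep_len)
    return ReadPair(pair.name, s1, q1, s2, q2)


def _low_quality_fraction(qual: str, min_q: int) -> float:
    q = _seq.phred_to_array(qual)
    return float(np.count_nonzero(q < min_q)) / max(len(q), 1)


def quality_filter(pairs, max_low_frac: float = 0.05, min_q: int = 30,
                   ) -> tuple[list[ReadPair], dict[str, int]]:
    """Keep pairs whose mates both have <= ``max_low_frac`` bases under
    ``min_q``; the boundary fraction itself is retained."""
    kept: list[ReadPair] = []
    log = {"input_pairs": 0, "discarded_pairs": 0, "retained_pairs": 0}
    for pair in pairs:
        log["input_pairs"] += 1
        if (_low_quality_fraction(pair.qual1, min_q) > max_low_frac
                or _low_quality_fraction(pair.qual2, min_q) > max_low_frac):
            log["discarded_pairs"] += 1
        else:
            kept.append(pair)
            log["retained_pairs"] += 1
    return kept, log


def preprocess_pairs(pairs, residues: list[str] | None = None, keep_len: int = 75,
                     max_low_frac: float = 0.05, min_q: int = 30,
                     ) -> tuple[list[ReadPair], dict[str, int]]:
    """Trim then quality-filter a stream of pairs; returns pairs + log."""
    trimmed = [trim_pair(p, residues, keep_len) for p in pairs]
    kept, log = quality_filter(trimmed, max_low_frac, min_q)
    log["trimmed_pairs"] = len(trimmed)
    return kept, log
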