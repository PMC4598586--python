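"""Context classification, pileup, methylation calls, SNP calls and masking."""

import numpy as np
import pandas as pd
import pytest

from mrrbs.bsalign import AlignmentRecord, align_reads, build_bs_index
from mrrbs.genome import ReferenceSet
from mrrbs.methcall import (CONTEXT_CG, CONTEXT_CHG, CONTEXT_CHH, call_levels,
                            call_snps, classify_cytosines, mask_sites, pileup)
from mrrbs.preprocess import preprocess_pairs
from mrrbs.simulate import ReadSimParams, apply_variants, simulate_ddrad_reads

from conftest import random_reference


class TestClassify:
    @pytest.mark.parametrize("seq,pos,strand,context", [
        ("ACGT", 1, "+", CONTEXT_CG),
        ("ACGT", 2, "-", CONTEXT_CG),   # bottom-strand C opposite the G
        ("ACAGT", 1, "+", CONTEXT_CHG),
        ("ACATT", 1, "+", CONTEXT_CHH),
    ])
    def test_textbook_contexts(self, seq, pos, strand, context):
        catalog = classify_cytosines(ReferenceSet({"c": seq}))
        arr = catalog.top["c"] if strand == "+" else catalog.bottom["c"]
        assert arr[pos] == context

    def test_counts_match_bruteforce(self):
        ref = random_reference(1, 3_000)
        catalog = classify_cytosines(ref)
        seq = ref["chr1"]
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        rc = "".join(comp[b] for b in reversed(seq))

        def brute(s):
            out = {}
            for i, b in enumerate(s):
                if b != "C":
                    continue
                if i + 1 < len(s) and s[i + 1] == "G":
                    out[i] = CONTEXT_CG
                elif i + 2 < len(s) and s[i + 2] == "G":
                    out[i] = CONTEXT_CHG
                elif i + 2 < len(s):
                    out[i] = CONTEXT_CHH
            return out

        top = brute(seq)
        bottom_rc = brute(rc)
        bottom = {len(seq) - 1 - i: c for i, c in bottom_rc.items()}
        assert {i: c for i, c in enumerate(catalog.top["chr1"]) if c} == top
        assert {i: c for i, c in enumerate(catalog.bottom["chr1"]) if c} == bottom
        # every classifiable cytosine lands in exactly one of the classes
        n_class = sum(catalog.counts().values())
        assert n_class == len(top) + len(bottom)


def _record(seq1, pos1, seq2=None, pos2=None, qual1=None, conv="CT", name="p"):
    seq2 = seq2 if seq2 is not None else seq1
    pos2 = pos2 if pos2 is not None else pos1
    qual1 = qual1 if qual1 is not None else "I" * len(seq1)
    return AlignmentRecord(name=name, chrom="c", pos1=pos1, pos2=pos2,
                           r1_strand="+", bs_strand="OT" if conv == "CT" else "OB",
                           conversion=conv, mismatches=0,
                           seq1_oriented=seq1, qual1_oriented=qual1,
                           seq2_oriented=seq2, qual2_oriented="I" * len(seq2))


class TestPileupAndCalls:
    ref = ReferenceSet({"c": "AACGTTAACGTT"})  # CG sites at 2 (+) and 3 (-)

    def _catalog(self):
        return classify_cytosines(self.ref)

    def test_single_methylated_base(self):
        rec = _record("ACGT", 1, seq2="ACGT", pos2=1)
        counts = pileup([rec], self._catalog(), self.ref)
        assert counts.meth_top["c"][2] == 1
        assert counts.unmeth_top["c"][2] == 0

    def test_mate_overlap_counts_once(self):
        # mates disagree at the overlapping CG site; read 1 wins
        rec = _record("ACGT", 1, seq2="ATGT", pos2=1)
        counts = pileup([rec], self._catalog(), self.ref)
        assert counts.meth_top["c"][2] == 1
        assert counts.unmeth_top["c"][2] == 0

    def test_low_quality_base_skipped(self):
        rec = _record("ACGT", 1, seq2="ACGT", pos2=1, qual1="I4II")  # '4' = Q19
        counts = pileup([rec], self._catalog(), self.ref)
        # read2 still provides the base at the non-overlapping? both mates at
        # same span: read1 Q19 overwrites -> skipped
        assert counts.meth_top["c"][2] == 0

    def test_unknown_chromosome_errors(self):
        rec = AlignmentRecord("p", "nope", 0, 0, "+", "OT", "CT", 0,
                              "ACGT", "IIII", "ACGT", "IIII")
        with pytest.raises(KeyError):
            pileup([rec], self._catalog(), self.ref)

    def test_depth_floor_and_levels(self):
        catalog = self._catalog()
        recs = [_record("ACGT", 1, name=f"m{i}") for i in range(7)]
        recs += [_record("ATGT", 1, name=f"u{i}") for i in range(3)]
        counts = pileup(recs, catalog, self.ref)
        calls = call_levels(counts, catalog, min_depth=10)
        row = calls.set_index(["pos", "strand"]).loc[(2, "+")]
        assert row["level"] == pytest.approx(0.7)
        # coverage 9 -> no call
        counts9 = pileup(recs[:9], catalog, self.ref)
        assert len(call_levels(counts9, catalog, min_depth=10)) == 0
        # all unmethylated -> level 0
        recs0 = [_record("ATGT", 1, name=f"z{i}") for i in range(10)]
        calls0 = call_levels(pileup(recs0, catalog, self.ref), catalog, 10)
        assert calls0.iloc[0]["level"] == 0.0

    def test_conservation_against_bruteforce(self):
        rng = np.random.default_rng(3)
        ref = random_reference(4, 2_000)
        catalog = classify_cytosines(ref)
        recs = []
        for i in range(300):
            p1 = int(rng.integers(0, 1800))
            p2 = min(p1 + int(rng.integers(0, 100)), 1925)
            s1 = ref["chr1"][p1:p1 + 75]
            s2 = ref["chr1"][p2:p2 + 75]
            conv = "CT" if rng.random() < 0.5 else "GA"
            recs.append(AlignmentRecord(f"r{i}", "chr1", p1, p2, "+",
                                        "OT" if conv == "CT" else "OB", conv, 0,
                                        s1, "I" * len(s1), s2, "I" * len(s2)))
        counts = pileup(recs, catalog, ref)
        # brute force: per pair, read1 wins at overlap, count informative bases
        meth = {}
        unmeth = {}
        for rec in recs:
            seen = {}
            for pos, base in zip(range(rec.pos2, rec.pos2 + len(rec.seq2_oriented)),
                                 rec.seq2_oriented):
                seen[pos] = base
            for pos, base in zip(range(rec.pos1, rec.pos1 + len(rec.seq1_oriented)),
                                 rec.seq1_oriented):
                seen[pos] = base
            for pos, base in seen.items():
                if rec.conversion == "CT" and catalog.top["chr1"][pos]:
                    if base == "C":
                        meth[("+", pos)] = meth.get(("+", pos), 0) + 1
                    elif base == "T":
                        unmeth[("+", pos)] = unmeth.get(("+", pos), 0) + 1
                elif rec.conversion == "GA" and catalog.bottom["chr1"][pos]:
                    if base == "G":
                        meth[("-", pos)] = meth.get(("-", pos), 0) + 1
                    elif base == "A":
                        unmeth[("-", pos)] = unmeth.get(("-", pos), 0) + 1
        for (strand, pos), n in meth.items():
            arr = counts.meth_top if strand == "+" else counts.meth_bottom
            assert arr["chr1"][pos] == n
        for (strand, pos), n in unmeth.items():
            arr = counts.unmeth_top if strand == "+" else counts.unmeth_bottom
            assert arr["chr1"][pos] == n
        total = sum(int(a.sum()) for a in
                    (counts.meth_top["chr1"], counts.unmeth_top["chr1"],
                     counts.meth_bottom["chr1"], counts.unmeth_bottom["chr1"]))
        assert total == sum(meth.values()) + sum(unmeth.values())


class TestConversionBias:
    def test_incomplete_conversion_bias_at_unmethylated_sites(self):
        """With conversion efficiency e < 1, a truly unmethylated site is
        read as methylated at rate 1 - e."""
        from mrrbs.simulate import (GenomeSpec, MethylationModel,
                                    generate_genome, generate_methylome,
                                    simulate_rrbs_reads)
        from mrrbs.preprocess import preprocess_pairs
        spec = GenomeSpec(n_chromosomes=1, chrom_length=60_000, n_genes=0,
                          n_tes=0, n_tandem_repeats=0, n_inverted_repeats=0,
                          seed=30)
        ref, ann = generate_genome(spec)
        means = {(c, x): 0.0 for c in
                 ("te", "exon", "intron", "promoter", "flank", "intergenic")
                 for x in ("CG", "CHG", "CHH")}
        truth = generate_methylome(ref, ann, MethylationModel(means=means),
                                   seed=31)
        from test_bsalign import _tiling_fragments
        frags = _tiling_fragments(ref, np.random.default_rng(32), n=40)
        params = ReadSimParams(bisulfite_conversion_efficiency=0.9,
                               sequencing_error_rate=0.0, degraded_fraction=0.0,
                               quality_sd=0.0, coverage_target=12.0, seed=33)
        sim = simulate_rrbs_reads(ref, truth, frags, params)
        pairs, _ = preprocess_pairs(sim.pairs)
        index = build_bs_index(ref)
        records, _ = align_reads(pairs, index)
        catalog = classify_cytosines(ref)
        counts = pileup(records, catalog, ref)
        calls = call_levels(counts, catalog, min_depth=10)
        total = (calls["meth"] + calls["unmeth"]).sum()
        observed = calls["meth"].sum() / total
        se = np.sqrt(0.1 * 0.9 / total)
        assert abs(observed - 0.1) < 4 * se


class TestSnpCallsAndMasking:
    def test_truth_set_recall_and_no_false_positives(self):
        ref = random_reference(5, 30_000)
        sample, variants = apply_variants(ref, 2e-3, seed=6)
        from test_bsalign import _tiling_fragments
        frags = _tiling_fragments(sample, np.random.default_rng(7), n=60)
        params = ReadSimParams(sequencing_error_rate=0.0, degraded_fraction=0.0,
                               quality_sd=0.0, coverage_target=6.0, seed=8)
        sim = simulate_ddrad_reads(sample, frags, params)
        pairs, _ = preprocess_pairs(sim.pairs)
        index = build_bs_index(ref)
        records, _ = align_reads(pairs, index, mode="plain")
        snps = call_snps(records, ref)
        called = set(zip(snps["chrom"], snps["pos"]))
        truth = set(zip(variants["chrom"], variants["pos"]))
        # no false positives under zero error
        assert called <= truth
        # full recall at covered true positions
        covered = np.zeros(30_000, dtype=bool)
        for rec in records:
            covered[rec.pos1:rec.pos1 + len(rec.seq1_oriented)] = True
            covered[rec.pos2:rec.pos2 + len(rec.seq2_oriented)] = True
        for chrom, pos in truth:
            if covered[pos]:
                assert (chrom, pos) in called

    def test_single_hq_read_calls_candidate(self):
        ref = ReferenceSet({"c": "A" * 50})
        rec = AlignmentRecord("p", "c", 10, 10, "+", "fwd", "raw", 1,
                              "AAAAGAAAAA", "I" * 10, "AAAAGAAAAA", "I" * 10)
        snps = call_snps([rec], ref)
        assert len(snps) == 1
        assert snps.iloc[0]["pos"] == 14
        assert snps.iloc[0]["alt"] == "G"
        # all-reference reads call nothing
        rec2 = AlignmentRecord("q", "c", 10, 10, "+", "fwd", "raw", 0,
                               "A" * 10, "I" * 10, "A" * 10, "I" * 10)
        assert len(call_snps([rec2], ref)) == 0

    def _calls(self):
        return pd.DataFrame({
            "chrom": ["c"] * 4,
            "pos": [10, 20, 30, 40],
            "strand": ["+", "+", "-", "+"],
            "context": ["CG", "CHH", "CHG", "CHH"],
            "meth": [5, 5, 5, 5], "unmeth": [5, 5, 5, 5],
            "level": [0.5] * 4,
        })

    def test_no_variants_identity(self):
        calls = self._calls()
        out, removed = mask_sites(calls, pd.DataFrame())
        pd.testing.assert_frame_equal(out, calls)
        assert sum(removed.values()) == 0

    def test_motif_window_rules(self):
        calls = self._calls()
        # SNP at the G of the CG site (pos 11) removes the site at 10
        v1 = pd.DataFrame({"chrom": ["c"], "pos": [11], "ref": ["G"], "alt": ["A"]})
        out, removed = mask_sites(calls, v1)
        assert 10 not in set(out["pos"]) and removed["CG"] == 1
        # SNP 3 bp downstream of a CHH site stays outside the window
        v2 = pd.DataFrame({"chrom": ["c"], "pos": [23], "ref": ["A"], "alt": ["T"]})
        out2, removed2 = mask_sites(calls, v2)
        assert len(out2) == 4 and sum(removed2.values()) == 0
        # minus-strand CHG window extends to lower coordinates
        v3 = pd.DataFrame({"chrom": ["c"], "pos": [28], "ref": ["A"], "alt": ["T"]})
        out3, removed3 = mask_sites(calls, v3)
        assert 30 not in set(out3["pos"]) and removed3["CHG"] == 1
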