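"""Synthetic-data generators: genomes, methylomes, variants, reads, expression."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from mrrbs import _seq
from mrrbs.digest import Fragment, double_digest, select_representation
from mrrbs.genome import ReferenceSet
from mrrbs.methcall import CONTEXT_CG, classify_cytosines
from mrrbs.simulate import (COMP_INDEX, ExpressionModel, GenomeSpec,
                            MethylationModel, PackingError, ReadSimParams,
                            apply_variants, generate_expression,
                            generate_genome, generate_methylome,
                            simulate_ddrad_reads, simulate_rrbs_reads)


class TestGenerateGenome:
    def test_empty_feature_sets(self):
        spec = GenomeSpec(n_chromosomes=1, chrom_length=10_000, n_genes=0,
                          n_tes=0, n_tandem_repeats=0, n_inverted_repeats=0, seed=0)
        ref, ann = generate_genome(spec)
        assert ref.length("chr1") == 10_000
        assert len(ann.genes) == len(ann.tes) == len(ann.repeats) == 0

    def test_deterministic_given_seed(self, small_spec):
        ref1, ann1 = generate_genome(small_spec)
        ref2, ann2 = generate_genome(small_spec)
        assert ref1.sequences == ref2.sequences
        pd.testing.assert_frame_equal(ann1.genes, ann2.genes)
        pd.testing.assert_frame_equal(ann1.tes, ann2.tes)
        ref3, _ = generate_genome(GenomeSpec(**{**small_spec.__dict__, "seed": 99}))
        assert ref3.sequences != ref1.sequences

    def test_pericentromeric_fraction_one_confines_te_midpoints(self):
        spec = GenomeSpec(n_chromosomes=1, chrom_length=200_000, n_genes=10,
                          n_tes=40, te_pericentromeric_fraction=1.0,
                          n_tandem_repeats=0, n_inverted_repeats=0, seed=3)
        ref, ann = generate_genome(spec)
        b_start, b_end = spec.central_block(200_000)
        mid = (ann.tes["start"] + ann.tes["end"]) // 2
        assert ((mid >= b_start) & (mid < b_end)).all()

    def test_structural_invariants(self, small_genome):
        ref, ann = small_genome
        ann.validate(ref)  # genes non-overlapping, features in bounds
        for seq in ref.sequences.values():
            assert set(seq) <= set("ACGT")
        # every gene's exons tile inward from the gene start
        for gid, ex in ann.exons.groupby("gene_id"):
            g = ann.genes.set_index("gene_id").loc[gid]
            assert ex["start"].min() == g["start"]
            assert ex["end"].max() == g["end"]

    def test_infeasible_packing_raises(self):
        spec = GenomeSpec(n_chromosomes=1, chrom_length=20_000, n_genes=40,
                          n_tes=0, n_tandem_repeats=0, n_inverted_repeats=0, seed=0)
        with pytest.raises(PackingError):
            generate_genome(spec)

    def test_gc_content_bounds_validated(self):
        with pytest.raises(ValueError):
            GenomeSpec(gc_content=1.5)


class TestGenerateMethylome:
    def test_all_zero_model_gives_zero_levels(self, small_genome):
        ref, ann = small_genome
        means = {(c, x): 0.0 for c in COMP_INDEX for x in ("CG", "CHG", "CHH")}
        truth = generate_methylome(ref, ann, MethylationModel(means=means), seed=0)
        for lv in list(truth.levels_top.values()) + list(truth.levels_bottom.values()):
            vals = lv[~np.isnan(lv)]
            assert (vals == 0.0).all()

    def test_two_point_te_mean_within_three_se(self):
        spec = GenomeSpec(n_chromosomes=1, chrom_length=400_000, n_genes=0,
                          n_tes=120, te_pericentromeric_fraction=1.0,
                          central_block_fraction=0.8, n_tandem_repeats=0,
                          n_inverted_repeats=0, seed=5)
        ref, ann = generate_genome(spec)
        model = MethylationModel.component_default()
        model.family[("te", "CG")] = "two_point"
        truth = generate_methylome(ref, ann, model, seed=6)
        means = truth.mean_by_component_context().set_index(["component", "context"])
        row = means.loc[("te", "CG")]
        n = row["count"]
        assert n > 10_000
        se = np.sqrt(0.88 * 0.12 / n)
        assert abs(row["mean"] - 0.88) < 3 * se

    def test_ccgg_both_strands(self):
        ref = ReferenceSet({"c": "CCGG"})
        from mrrbs.genome import AnnotationSet
        truth = generate_methylome(ref, AnnotationSet(),
                                   MethylationModel.component_default(), seed=0)
        # the CG dinucleotide contributes one CG record per strand
        assert truth.contexts_top["c"][1] == CONTEXT_CG
        assert truth.contexts_bottom["c"][2] == CONTEXT_CG
        assert not np.isnan(truth.levels_top["c"][1])
        assert not np.isnan(truth.levels_bottom["c"][2])

    def test_contexts_equal_classify_cytosines(self, small_genome, small_truth):
        ref, _ = small_genome
        catalog = classify_cytosines(ref)
        for chrom in ref.names():
            np.testing.assert_array_equal(small_truth.contexts_top[chrom],
                                          catalog.top[chrom])
            np.testing.assert_array_equal(small_truth.contexts_bottom[chrom],
                                          catalog.bottom[chrom])

    def test_ordering_invariant_enforced(self):
        means = {(c, x): 0.5 for c in COMP_INDEX for x in ("CG", "CHG", "CHH")}
        means[("te", "CHH")] = 0.9  # CHH above CG
        with pytest.raises(ValueError):
            MethylationModel(means=means)


class TestApplyVariants:
    def test_rate_zero_identity(self, small_genome):
        ref, _ = small_genome
        sample, variants = apply_variants(ref, 0.0, seed=0)
        assert sample.sequences == ref.sequences
        assert len(variants) == 0

    def test_rate_recovers_expected_count(self):
        from conftest import random_reference
        ref = random_reference(7, 1_000_000)
        _, variants = apply_variants(ref, 1e-3, seed=8)
        se = np.sqrt(1_000_000 * 1e-3)
        assert abs(len(variants) - 1000) < 3 * se

    def test_substitutions_only_and_consistent(self):
        from conftest import random_reference
        ref = random_reference(9, 50_000)
        sample, variants = apply_variants(ref, 2e-3, seed=10)
        assert ref.total_length == sample.total_length
        diff = {i for i, (a, b) in enumerate(zip(ref["chr1"], sample["chr1"]))
                if a != b}
        assert diff == set(variants["pos"])
        for v in variants.itertuples(index=False):
            assert ref["chr1"][v.pos] == v.ref
            assert sample["chr1"][v.pos] == v.alt
            assert v.ref != v.alt


def _selected_fragments(ref):
    return select_representation(double_digest(ref))


class TestSimulateRrbsReads:
    def test_full_conversion_removes_cytosines(self, small_genome, clean_sim_params):
        ref, ann = small_genome
        means = {(c, x): 0.0 for c in COMP_INDEX for x in ("CG", "CHG", "CHH")}
        truth = generate_methylome(ref, ann, MethylationModel(means=means), seed=0)
        params = ReadSimParams(**{**clean_sim_params.__dict__,
                                  "bisulfite_conversion_efficiency": 1.0,
                                  "coverage_target": 2.0})
        sim = simulate_rrbs_reads(ref, truth, _selected_fragments(ref), params)
        assert len(sim.pairs) > 50
        for p in sim.pairs:
            bs = p.name.split(":")[4]
            if bs in ("OT", "OB"):     # read1 is the converted strand itself
                assert "C" not in p.seq1
                assert "G" not in p.seq2
            else:                      # read1 is the PCR complement
                assert "G" not in p.seq1
                assert "C" not in p.seq2

    def test_fully_methylated_reads_are_verbatim(self, small_genome, clean_sim_params):
        ref, ann = small_genome
        means = {(c, x): 1.0 if x == "CG" else 1.0
                 for c in COMP_INDEX for x in ("CG", "CHG", "CHH")}
        truth = generate_methylome(ref, ann, MethylationModel(means=means), seed=0)
        params = ReadSimParams(**{**clean_sim_params.__dict__, "coverage_target": 1.0})
        sim = simulate_rrbs_reads(ref, truth, _selected_fragments(ref), params)
        for p in sim.pairs[:200]:
            chrom, s, e, _, _, _ = p.name.split(":")
            frag = ref[chrom][int(s):int(e)]
            assert p.seq1 in frag or p.seq1 in _seq.revcomp(frag)
            assert p.seq2 in frag or p.seq2 in _seq.revcomp(frag)

    def test_informative_coverage_near_target(self, small_genome, small_truth,
                                              clean_sim_params):
        ref, _ = small_genome
        params = ReadSimParams(**{**clean_sim_params.__dict__, "coverage_target": 20.0})
        frags = _selected_fragments(ref)
        sim = simulate_rrbs_reads(ref, small_truth, frags, params)
        # informative depth at a top-strand site = molecules drawn from '+'
        per_frag_top = {}
        for p in sim.pairs:
            chrom, s, e, src, _, _ = p.name.split(":")
            key = (chrom, int(s))
            per_frag_top.setdefault(key, 0)
            if src == "+":
                per_frag_top[key] += 1
        mean_depth = np.mean(list(per_frag_top.values()))
        assert abs(mean_depth - 20.0) / 20.0 < 0.2

    def test_short_fragments_skipped_and_determinism(self, small_genome,
                                                     small_truth, clean_sim_params):
        ref, _ = small_genome
        frags = [Fragment("chr1", 0, 20, "SacI", "MseI"),
                 Fragment("chr1", 1000, 1400, "SacI", "MseI")]
        sim1 = simulate_rrbs_reads(ref, small_truth, frags, clean_sim_params)
        sim2 = simulate_rrbs_reads(ref, small_truth, frags, clean_sim_params)
        assert sim1.skipped_fragments == 1
        assert sim1.pairs == sim2.pairs


class TestSimulateDdradReads:
    def test_error_free_reads_are_substrings(self, small_genome, clean_sim_params):
        ref, _ = small_genome
        params = ReadSimParams(**{**clean_sim_params.__dict__, "coverage_target": 2.0})
        sim = simulate_ddrad_reads(ref, _selected_fragments(ref), params)
        genome = ref["chr1"]
        rc = _seq.revcomp(genome)
        for p in sim.pairs[:200]:
            assert p.seq1 in genome or p.seq1 in rc
            assert p.seq2 in genome or p.seq2 in rc

    def test_read_count_tracks_request(self, small_genome, clean_sim_params):
        ref, _ = small_genome
        frags = _selected_fragments(ref)
        params = ReadSimParams(**{**clean_sim_params.__dict__, "coverage_target": 10.0})
        sim = simulate_ddrad_reads(ref, frags, params)
        expected = 2 * 10.0 * len(frags)
        assert abs(len(sim.pairs) - expected) < 4 * np.sqrt(expected)
        assert sim.pairs == simulate_ddrad_reads(ref, frags, params).pairs


class TestGenerateExpression:
    def test_negative_coupling_gives_negative_rank_correlation(
            self, small_genome, small_truth):
        ref, ann = small_genome
        model = ExpressionModel(methylation_coupling=-6.0, dispersion=0.8, seed=1)
        table = generate_expression(ann, small_truth, model)
        sub = table.dropna()
        rho, p = sps.spearmanr(sub["gene_cg_methylation"], sub["rpkm"])
        assert rho < 0
        assert (table["rpkm"] >= 0).all()

    def test_zero_dispersion_is_deterministic_stratum_mean(self, small_genome,
                                                           small_truth):
        ref, ann = small_genome
        model = ExpressionModel(methylation_coupling=0.0, dispersion=0.0, seed=2)
        table = generate_expression(ann, small_truth, model).merge(
            ann.genes, on="gene_id")
        sub_eff = dict(model.subgenome_effects)
        copy_eff = dict(model.copy_effects)
        for r in table.itertuples(index=False):
            expected = 2.0 ** (model.base_log2 + sub_eff[r.subgenome]
                               + copy_eff[r.copy_class])
            assert r.rpkm == pytest.approx(expected)

    def test_null_model_class_balance(self, small_genome, small_truth):
        ref, ann = small_genome
        model = ExpressionModel(methylation_coupling=0.0,
                                subgenome_effects=(("LF", 0.0), ("MF1", 0.0),
                                                   ("MF2", 0.0)),
                                copy_effects=((1, 0.0), (2, 0.0), (3, 0.0)),
                                dispersion=2.0, seed=3)
        table = generate_expression(ann, small_truth, model).merge(
            ann.genes, on="gene_id")
        from mrrbs.stratify import bin_expression
        classes = bin_expression(table)
        tab = pd.crosstab(classes["subgenome"], classes["expr_class"])
        if tab.shape == (3, 3):
            _, p, _, _ = sps.chi2_contingency(tab)
            assert p > 1e-4
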