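"""Cis/trans assignment, clumping, locus aggregation, crossmap filter, FDR."""

import numpy as np
import pandas as pd
import pytest

from transqtl.io import CrossmapTable, GeneRecord
from transqtl.loci import (
    LocusThresholds,
    aggregate_loci,
    call_candidate_loci,
    classify_cis_trans,
    clump_per_gene,
    crossmap_filter,
    per_locus_fdr,
)

TH = LocusThresholds()


class TestClassifyCisTrans:
    def test_other_chromosome_is_trans(self):
        herc5_like = GeneRecord("HERC5", "chr4", 88_600_000, 88_650_000)
        assert classify_cis_trans("chr22", 18_166_589, herc5_like) == "trans"

    def test_window_boundary_is_inclusive(self):
        gene = GeneRecord("g", "chr1", 10_000_000, 10_050_000)
        assert classify_cis_trans("chr1", 10_000_000 - 4_900_000, gene) == "cis"
        assert classify_cis_trans("chr1", 10_000_000 - 5_000_000, gene) == "cis"
        assert classify_cis_trans("chr1", 10_000_000 - 5_000_001, gene) == "trans"

    def test_unannotated_gene_raises(self):
        with pytest.raises(ValueError):
            classify_cis_trans("chr1", 100, None)


def _stats(rows, p_column="p_fixed"):
    return pd.DataFrame(
        [
            {
                "variant_id": f"{chrom}_{pos}_A_G",
                "chrom": chrom,
                "pos": pos,
                "ref": "A",
                "alt": "G",
                "gene_id": gene,
                "beta_fixed": beta,
                p_column: p,
            }
            for chrom, pos, gene, p, beta in rows
        ]
    )


class TestClumping:
    def test_hand_traced_greedy_rule(self):
        stats = _stats(
            [
                ("chr1", 10_000_000, "g", 1e-15, 1.0),
                ("chr1", 11_000_000, "g", 1e-13, 1.0),
                ("chr1", 14_000_000, "g", 1e-12, 1.0),
            ]
        )
        leads = clump_per_gene(stats)
        assert list(leads["pos"]) == [10_000_000, 14_000_000]

    def test_no_leads_above_suggestive_threshold(self):
        stats = _stats([("chr1", 1_000_000, "g", 5e-11, 1.0)])
        assert clump_per_gene(stats).empty

    def test_single_suggestive_variant(self):
        stats = _stats([("chr1", 1_000_000, "g", 1e-12, 1.0)])
        assert len(clump_per_gene(stats)) == 1

    def test_leads_are_pairwise_separated(self):
        rng = np.random.default_rng(31)
        rows = [
            ("chr1", int(pos), "g", float(p), 1.0)
            for pos, p in zip(
                rng.integers(1, 60_000_000, 200),
                10 ** rng.uniform(-20, -5, 200),
            )
        ]
        leads = clump_per_gene(_stats(rows))
        pos = np.sort(leads["pos"].to_numpy())
        assert (np.diff(pos) > TH.clump_radius).all()
        assert (leads["p_fixed"] <= TH.lead_p_max).all()

    def test_empty_input(self):
        assert clump_per_gene(_stats([])).empty


def _annotation():
    return {
        "gA": GeneRecord("gA", "chr2", 1_000_000, 1_020_000),
        "gB": GeneRecord("gB", "chr2", 50_000_000, 50_020_000),
        "gC": GeneRecord("gC", "chr3", 9_000_000, 9_020_000),
        "cisP": GeneRecord("cisP", "chr1", 10_500_000, 10_520_000),
        "cisFar": GeneRecord("cisFar", "chr1", 13_000_000, 13_020_000),
    }


class TestAggregation:
    def test_nearby_leads_merge_with_smallest_p_lead(self):
        leads = _stats(
            [
                ("chr1", 10_000_000, "gA", 1e-14, 0.5),
                ("chr1", 10_400_000, "gB", 1e-12, 0.4),
            ]
        )
        meta = _stats(
            [
                ("chr1", 10_000_000, "gA", 1e-14, 0.5),
                ("chr1", 10_000_000, "gB", 1e-9, 0.4),
                ("chr1", 10_400_000, "gB", 1e-12, 0.4),
            ]
        )
        loci = aggregate_loci(leads, meta, _annotation())
        assert len(loci) == 1
        assert loci[0].pos == 10_000_000
        assert set(loci[0].members["gene_id"]) == {"gA", "gB"}
        assert loci[0].lead_gene == "gA"

    def test_different_chromosomes_stay_separate(self):
        leads = _stats(
            [
                ("chr1", 10_000_000, "gA", 1e-14, 0.5),
                ("chr2", 10_000_000, "gC", 1e-12, 0.4),
            ]
        )
        loci = aggregate_loci(leads, leads, _annotation())
        assert len(loci) == 2

    def test_shared_lead_collects_all_genes(self):
        genes = ["gA", "gB", "gC"]
        rows = [("chr1", 10_000_000, g, 1e-13, 0.3) for g in genes]
        loci = aggregate_loci(_stats(rows), _stats(rows), _annotation())
        assert len(loci) == 1
        assert set(loci[0].members["gene_id"]) == set(genes)


class TestCrossmapFilter:
    def test_high_score_with_nearby_coding_gene_fails(self):
        cm = CrossmapTable()
        cm.set("target", "cisP", 1.2)
        ok, reason = crossmap_filter(
            "target", "chr1", 10_500_000 + 800_000, _annotation(), cm
        )
        assert not ok and reason == "cisP"

    def test_low_score_passes(self):
        cm = CrossmapTable()
        cm.set("target", "cisP", 0.5)
        ok, _ = crossmap_filter("target", "chr1", 11_000_000, _annotation(), cm)
        assert ok

    def test_gene_outside_window_is_ignored(self):
        cm = CrossmapTable()
        cm.set("target", "cisFar", 1.2)
        # cisFar is 2.0 Mb from the lead: outside the 1.5 Mb window
        ok, _ = crossmap_filter("target", "chr1", 11_000_000, _annotation(), cm)
        assert ok

    def test_non_coding_cis_genes_are_ignored(self):
        ann = dict(_annotation())
        ann["cisP"] = GeneRecord("cisP", "chr1", 10_500_000, 10_520_000,
                                 biotype="lincRNA")
        cm = CrossmapTable()
        cm.set("target", "cisP", 5.0)
        ok, _ = crossmap_filter("target", "chr1", 11_000_000, ann, cm)
        assert ok

    def test_missing_table_disables_filter(self):
        ok, _ = crossmap_filter("target", "chr1", 11_000_000, _annotation(), None)
        assert ok


class TestCandidacy:
    def _locus(self, lead_p, n_pass, n_fail=0):
        rows = [("chr1", 10_000_000, f"t{i}", 1e-9, 0.3) for i in range(n_pass)]
        rows += [("chr1", 10_000_000, f"f{i}", 1e-9, 0.3) for i in range(n_fail)]
        rows[0] = ("chr1", 10_000_000, rows[0][2], lead_p, 0.3)
        ann = {
            g: GeneRecord(g, "chr5", 1_000_000 + 100_000 * i, 1_020_000 + 100_000 * i)
            for i, g in enumerate(r[2] for r in rows)
        }
        ann["cisX"] = GeneRecord("cisX", "chr1", 10_100_000, 10_120_000)
        cm = CrossmapTable()
        for i in range(n_fail):
            cm.set(f"f{i}", "cisX", 2.0)
        stats = _stats(rows)
        loci = aggregate_loci(stats, stats, ann)
        return call_candidate_loci(loci, ann, cm)[0]

    def test_five_passing_targets_make_a_candidate(self):
        locus = self._locus(1e-12, n_pass=5)
        assert locus.n_targets_sig == 5
        assert locus.is_candidate

    def test_four_passing_targets_do_not(self):
        assert not self._locus(1e-12, n_pass=4).is_candidate

    def test_weak_lead_does_not(self):
        assert not self._locus(5e-11, n_pass=6).is_candidate

    def test_crossmap_failures_do_not_count(self):
        locus = self._locus(1e-12, n_pass=4, n_fail=3)
        assert locus.n_targets_sig == 4
        assert not locus.is_candidate


class TestPerLocusFdr:
    def test_bh_hand_example(self):
        ann = {
            f"g{i}": GeneRecord(f"g{i}", "chr9", 1_000_000 * (i + 1),
                                1_000_000 * (i + 1) + 1000)
            for i in range(4)
        }
        meta = _stats(
            [
                ("chr1", 5_000_000, "g0", 0.001, 0.2),
                ("chr1", 5_000_000, "g1", 0.01, 0.2),
                ("chr1", 5_000_000, "g2", 0.03, 0.2),
                ("chr1", 5_000_000, "g3", 0.8, 0.2),
            ]
        )
        out = per_locus_fdr("chr1_5000000_A_G", meta, ann)
        assert np.allclose(out["qvalue"], [0.004, 0.02, 0.04, 0.8])
        assert out["significant"].tolist() == [True, True, True, False]

    def test_cis_window_genes_are_excluded(self):
        ann = {
            "cis": GeneRecord("cis", "chr1", 5_100_000, 5_200_000),
            "far": GeneRecord("far", "chr7", 1_000_000, 1_001_000),
        }
        meta = _stats(
            [
                ("chr1", 5_000_000, "cis", 1e-10, 0.5),
                ("chr1", 5_000_000, "far", 0.02, 0.3),
            ]
        )
        out = per_locus_fdr("chr1_5000000_A_G", meta, ann)
        assert out["gene_id"].tolist() == ["far"]

    def test_empty_universe_raises(self):
        ann = {"cis": GeneRecord("cis", "chr1", 5_100_000, 5_200_000)}
        meta = _stats([("chr1", 5_000_000, "cis", 1e-10, 0.5)])
        with pytest.raises(ValueError):
            per_locus_fdr("chr1_5000000_A_G", meta, ann)

    def test_missing_lead_raises(self):
        meta = _stats([("chr1", 5_000_000, "g", 0.5, 0.1)])
        with pytest.raises(ValueError):
            per_locus_fdr("chr9_1_A_G", meta, {})
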