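"""Enhancer calling, TAD pairing, accessibility dynamics, eRNA, shuffling."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dvburst.containers import CountTable
from dvburst.enhancers import (
    assign_enhancers,
    classify_accessibility,
    exclude_tss_regions,
    predict_expression,
    quantify_erna,
    score_regions,
    shuffle_regions,
)
from dvburst.genome import GeneModel, GenomicInterval, TadDomain
from dvburst.latent import LatentAxes
from dvburst.simulate import simulate_toy_genome


def _region_tables(rng, n_regions=100, boost_idx=(), boost_cond="A"):
    samples = [f"{c}_r{i}" for c in ("A", "B", "C") for i in (1, 2)]
    cond_of = {s: s.split("_")[0] for s in samples}
    names = [f"r{i:03d}" for i in range(n_regions)]
    tables = {}
    for assay in ("ATAC", "CBP", "H3K27ac"):
        base = rng.uniform(50, 500, size=n_regions)
        mat = np.zeros((n_regions, 6))
        for j, s in enumerate(samples):
            mu = base.copy()
            if cond_of[s] == boost_cond:
                mu[list(boost_idx)] *= 8.0
            mat[:, j] = rng.poisson(mu)
        tables[assay] = CountTable(
            pd.DataFrame(mat, index=names, columns=samples), cond_of
        )
    return tables


class TestScoreRegions:
    def test_top_fraction_count(self, rng):
        tables = _region_tables(rng, 100, boost_idx=range(8), boost_cond="A")
        scores = score_regions(tables, top_fraction=0.05)
        for assay in tables:
            flagged = scores.candidates[
                (scores.candidates["condition"] == "A") & scores.candidates[f"top_{assay}"]
            ]
            assert len(flagged) == 5

    def test_combined_is_sum_of_assay_z(self, rng):
        tables = _region_tables(rng, 50, boost_idx=range(4))
        scores = score_regions(tables)
        z = scores.z.pivot_table(index=["region", "condition"], columns="assay", values="z")
        comb = scores.combined.set_index(["region", "condition"])["combined_score"]
        np.testing.assert_allclose(z.sum(axis=1).loc[comb.index], comb, atol=1e-12)

    def test_too_few_regions_rejected(self, rng):
        tables = _region_tables(rng, 10)
        with pytest.raises(ValueError, match="20"):
            score_regions(tables)

    def test_planted_enhancers_recovered(self):
        toy = simulate_toy_genome(coupling_r=0.9, seed=11)
        regions = exclude_tss_regions(toy.all_regions, toy.genes)
        tables = {
            a: t.subset_entities([r.name for r in regions])
            for a, t in toy.region_counts.items()
        }
        scores = score_regions(tables)
        hits = [
            row["name"] in scores.candidate_regions(row["condition"])
            for _, row in toy.truth.enhancers.iterrows()
        ]
        assert np.mean(hits) >= 0.9


class TestExcludeTss:
    def _gene(self, tss):
        return GeneModel("g", "c", tss, "+", ())

    def test_region_spanning_tss_removed(self):
        regions = [GenomicInterval("c", 950, 1050, ".", "hit")]
        assert exclude_tss_regions(regions, [self._gene(1000)]) == []

    def test_region_just_outside_flank_kept(self):
        regions = [GenomicInterval("c", 1150, 1250, ".", "edge")]
        assert len(exclude_tss_regions(regions, [self._gene(1000)], flank=150)) == 1

    def test_no_genes_identity(self):
        regions = [GenomicInterval("c", 0, 100, ".", "a")]
        assert exclude_tss_regions(regions, []) == regions


class TestAssignEnhancers:
    def _setup(self):
        tads = [
            TadDomain(GenomicInterval("c", 0, 10_000, ".", "t0"), "t0"),
            TadDomain(GenomicInterval("c", 10_000, 20_000, ".", "t1"), "t1"),
        ]
        genes = [
            GeneModel("gA", "c", 5_000, "+", ()),
            GeneModel("gB", "c", 15_000, "+", ()),
        ]
        regions = [
            GenomicInterval("c", 2_000, 2_500, ".", "e_same_tad"),
            GenomicInterval("c", 12_000, 12_500, ".", "e_other_tad"),
            GenomicInterval("c", 4_300, 4_500, ".", "e_proximal"),
        ]
        return tads, genes, regions

    def test_same_tad_same_condition_pairs(self):
        tads, genes, regions = self._setup()
        out = assign_enhancers(
            {"A": ["e_same_tad"]}, regions, {"gA": "A", "gB": "A"}, genes, tads
        )
        assert [(a.enhancer.name, a.gene_id) for a in out] == [("e_same_tad", "gA")]

    def test_distance_700_is_proximal(self):
        tads, genes, regions = self._setup()
        # e_proximal ends at 4500; distance to TSS 5000 is 5000-4499 = 501
        out = assign_enhancers(
            {"A": ["e_proximal"]}, regions, {"gA": "A"}, genes, tads, proximal_bp=501
        )
        assert out[0].proximity == "proximal"
        out = assign_enhancers(
            {"A": ["e_proximal"]}, regions, {"gA": "A"}, genes, tads, proximal_bp=500
        )
        assert out[0].proximity == "distal"

    def test_condition_mismatch_not_paired(self):
        tads, genes, regions = self._setup()
        out = assign_enhancers(
            {"B": ["e_same_tad"]}, regions, {"gA": "A"}, genes, tads
        )
        assert out == []

    def test_order_invariance(self):
        tads, genes, regions = self._setup()
        dv = {"gA": "A", "gB": "A"}
        cands = {"A": ["e_same_tad", "e_other_tad", "e_proximal"]}
        out1 = assign_enhancers(cands, regions, dv, genes, tads)
        out2 = assign_enhancers(
            {"A": list(reversed(cands["A"]))}, list(reversed(regions)),
            dict(reversed(dv.items())), list(reversed(genes)), tads,
        )
        assert out1 == out2


class TestPredictExpression:
    def test_exact_linear_data(self):
        tads = [TadDomain(GenomicInterval("c", 0, 100_000, ".", "t0"), "t0")]
        genes = [GeneModel(f"g{i}", "c", 1000 + 2000 * i, "+", ()) for i in range(5)]
        regions = [
            GenomicInterval("c", 50_000 + 600 * i, 50_500 + 600 * i, ".", f"e{i}")
            for i in range(5)
        ]
        pairs = assign_enhancers(
            {"A": [r.name for r in regions[:1]]}, regions,
            {"g0": "A"}, genes, tads,
        )
        # build a fully synthetic linear score/z relation over 5 pairs
        combined = pd.DataFrame(
            {"region": [f"e{i}" for i in range(5)], "condition": "A",
             "combined_score": np.arange(5.0)}
        )
        gene_z = pd.DataFrame({"A": 2.0 * np.arange(5.0) + 1.0},
                              index=[f"g{i}" for i in range(5)])
        all_pairs = assign_enhancers(
            {"A": [r.name for r in regions]}, regions,
            {f"g{i}": "A" for i in range(5)}, genes, tads,
        )
        # keep one pair per enhancer index to make the relation exact
        keep = [a for a in all_pairs if a.enhancer.name[1] == a.gene_id[1]]
        slope, intercept, r2, p = predict_expression(keep, combined, gene_z, "A")
        assert slope == pytest.approx(2.0)
        assert intercept == pytest.approx(1.0)
        assert r2 == pytest.approx(1.0)

    def test_null_pairs_have_low_r2(self, rng):
        hits = 0
        for trial in range(20):
            x = rng.normal(size=200)
            y = rng.normal(size=200)
            r2 = stats.linregress(x, y).rvalue ** 2
            hits += r2 < 0.05
        assert hits >= 19

    def test_known_coupling_recovered(self):
        """Combined chromatin score predicts expression with R^2 near the
        planted coupling^2 = 0.81."""
        r2s = []
        for seed in (0, 1, 2):
            toy = simulate_toy_genome(coupling_r=0.9, seed=seed)
            regions = exclude_tss_regions(toy.all_regions, toy.genes)
            tables = {
                a: t.subset_entities([r.name for r in regions])
                for a, t in toy.region_counts.items()
            }
            scores = score_regions(tables)
            gz = LatentAxes(toy.gene_counts).fit().z_matrix()
            dv = dict(zip(toy.truth.genes.gene_id, toy.truth.genes.condition))
            pairs = assign_enhancers(
                {c: scores.candidate_regions(c) for c in toy.gene_counts.conditions},
                regions, dv, toy.genes, toy.tads,
            )
            for c in toy.gene_counts.conditions:
                r2s.append(predict_expression(pairs, scores.combined, gz, c)[2])
        assert abs(np.mean(r2s) - 0.81) < 0.1


class TestNoiselessLimit:
    def test_full_recovery_and_perfect_r2(self):
        toy = simulate_toy_genome(coupling_r=1.0, noiseless=True, seed=4)
        regions = exclude_tss_regions(toy.all_regions, toy.genes)
        tables = {
            a: t.subset_entities([r.name for r in regions])
            for a, t in toy.region_counts.items()
        }
        scores = score_regions(tables)
        te = toy.truth.enhancers
        assert all(
            row["name"] in scores.candidate_regions(row["condition"])
            for _, row in te.iterrows()
        )
        gz = LatentAxes(toy.gene_counts).fit().z_matrix()
        dv = dict(zip(toy.truth.genes.gene_id, toy.truth.genes.condition))
        pairs = assign_enhancers(
            {c: scores.candidate_regions(c) for c in toy.gene_counts.conditions},
            regions, dv, toy.genes, toy.tads,
        )
        planted = set(zip(te["name"], te["gene_id"]))
        assert {(a.enhancer.name, a.gene_id) for a in pairs} == planted
        for c in toy.gene_counts.conditions:
            assert predict_expression(pairs, scores.combined, gz, c)[2] > 0.999


class TestAccessibility:
    @pytest.mark.parametrize(
        "fc,expected",
        [(0.5, "gained"), (-0.5, "lost"), (0.49, "stable"), (-0.49, "stable"),
         (1.7, "gained"), (-2.0, "lost"), (0.0, "stable")],
    )
    def test_class_boundaries_inclusive(self, fc, expected):
        from dvburst.enhancers import accessibility_class

        assert accessibility_class(fc) == expected

    def test_fc_computed_with_pseudocount(self):
        df = pd.DataFrame({"3h": [99.0], "4h": [199.0]}, index=["e1"])
        (out,) = classify_accessibility(df, "A")
        assert out.log2_fc == pytest.approx(1.0)
        assert out.dynamics_class == "gained"

    def test_per_timepoint_classes(self):
        df = pd.DataFrame({"3h": [100.0], "4h": [300.0], "5h": [30.0]}, index=["e1"])
        out = classify_accessibility(df, "A")
        assert [o.dynamics_class for o in out] == ["gained", "lost"]


class TestErna:
    def _reads(self, n_plus, n_minus, start=1000):
        reads = []
        for i in range(n_plus):
            reads.append(GenomicInterval("c", start + i, start + i + 1, "+", f"p{i}"))
        for i in range(n_minus):
            reads.append(GenomicInterval("c", start + i, start + i + 1, "-", f"m{i}"))
        return reads

    def test_genic_counts_antisense_only(self):
        enh = GenomicInterval("c", 900, 1200, ".", "e")
        counts, _ = quantify_erna(
            enh, {"A": self._reads(10, 4)}, genic=True, host_strand="+"
        )
        assert counts["A"] == 4

    def test_intergenic_counts_both_strands(self):
        enh = GenomicInterval("c", 900, 1200, ".", "e")
        counts, _ = quantify_erna(enh, {"A": self._reads(10, 4)}, genic=False)
        assert counts["A"] == 14

    def test_zero_counts_fc_zero(self):
        enh = GenomicInterval("c", 900, 1200, ".", "e")
        _, fcs = quantify_erna(enh, {"A": [], "B": []}, genic=False)
        assert fcs[("A", "B")] == 0.0

    def test_genic_requires_host_strand(self):
        enh = GenomicInterval("c", 900, 1200, ".", "e")
        with pytest.raises(ValueError, match="host_strand"):
            quantify_erna(enh, {"A": []}, genic=True)


class TestShuffle:
    def test_lengths_preserved_and_deterministic(self, rng):
        regions = [
            GenomicInterval("c", int(s), int(s) + int(w), ".", f"r{i}")
            for i, (s, w) in enumerate(zip(rng.integers(0, 5000, 20), rng.integers(50, 400, 20)))
        ]
        sizes = {"c": 100_000}
        out1 = shuffle_regions(regions, sizes, seed=5)
        out2 = shuffle_regions(regions, sizes, seed=5)
        assert out1 == out2
        assert [r.length for r in out1] == [r.length for r in regions]

    def test_exclusion_respected(self):
        regions = [GenomicInterval("c", 0, 100, ".", "r")] * 1
        exclude = [GenomicInterval("c", 0, 90_000, ".", "x")]
        out = shuffle_regions(regions, {"c": 100_000}, seed=1, exclude=exclude)
        assert not out[0].overlaps(exclude[0])

    def test_impossible_placement_errors(self):
        regions = [GenomicInterval("c", 0, 100, ".", "r")]
        exclude = [GenomicInterval("c", 0, 100_000, ".", "x")]
        with pytest.raises(ValueError, match="place"):
            shuffle_regions(regions, {"c": 100_000}, seed=1, exclude=exclude)

    def test_midpoints_uniform(self):
        region = [GenomicInterval("c", 0, 100, ".", "r")]
        sizes = {"c": 20_000}
        mids = []
        for seed in range(10_000):
            (out,) = shuffle_regions(region, sizes, seed=seed)
            mids.append(out.midpoint)
        counts, _ = np.histogram(mids, bins=20, range=(0, 20_000))
        p = stats.chisquare(counts).pvalue
        assert p > 0.001
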