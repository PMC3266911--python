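import math

import numpy as np
import pandas as pd
import pytest

from oncoamp.integrate import (
    CorrelationResult,
    GeneModel,
    OverAmpSummary,
    apply_table2_filter,
    correlation_from_published,
    expand_counts,
    gene_copy_number,
    pearson_filter,
    rank_candidates,
    status_matrix,
    summarize_oa,
)
from oncoamp.simulate import simulate_cohort, simulate_expression

from .conftest import make_config

# printed summary counts: gene -> (A, O, OA, published pct)
TABLE1 = {
    "SHMT1": (17, 15, 13, 76.5),
    "PMP22": (16, 14, 12, 75.0),
    "RASD1": (18, 13, 12, 66.7),
    "TOP3A": (17, 12, 11, 64.7),
    "PRPSAP2": (16, 10, 10, 62.5),
    "COPS3": (18, 12, 11, 61.1),
    "GRAP": (17, 12, 10, 58.8),
    "C17orf39": (18, 10, 10, 55.6),
    "RICH2": (17, 11, 9, 52.9),
    "ALKBH5": (17, 10, 9, 52.9),
    "C17orf45": (18, 10, 9, 50.0),
}

# printed correlation rows: gene -> (R, two-sided P)
TABLE2 = {
    "C17orf39": (0.77, 0.00003),
    "RICH2": (0.75, 0.00009),
    "C17orf45": (0.74, 0.0001),
    "TOP3A": (0.73, 0.0001),
    "COPS3": (0.72, 0.0002),
    "SHMT1": (0.67, 0.0007),
    "PRPSAP2": (0.64, 0.001),
    "PMP22": (0.62, 0.002),
    "RASD1": (0.49, 0.02),
    "GRAP": (-0.13, 0.6),
    "ALKBH5": (-0.16, 0.5),
}


def pearson_oracle(x, y):
    """Direct-summation product-moment formula."""
    n = len(x)
    sx, sy = sum(x), sum(y)
    sxx = sum(v * v for v in x)
    syy = sum(v * v for v in y)
    sxy = sum(a * b for a, b in zip(x, y))
    num = n * sxy - sx * sy
    den = math.sqrt(n * sxx - sx * sx) * math.sqrt(n * syy - sy * sy)
    return num / den


class TestGeneCopyNumber:
    probes = pd.DataFrame(
        {"probe_id": ["p1", "p2", "p3", "p4"], "chrom": ["17"] * 4,
         "pos": [100, 200, 300, 1000]}
    )

    def test_overlapping_probes_median(self):
        gene = GeneModel(name="G", chrom="17", start=50, end=350)
        assert gene_copy_number(gene, [4, 4, 6, 8], self.probes) == 4

    def test_even_count_lower_median(self):
        gene = GeneModel(name="G", chrom="17", start=150, end=350)
        assert gene_copy_number(gene, [0, 2, 6, 8], self.probes) == 2

    def test_no_overlap_nearest(self):
        gene = GeneModel(name="G", chrom="17", start=400, end=500)
        # p3 at 300 is 100 away from start; p4 at 1000 is 501 from end-1
        assert gene_copy_number(gene, [4, 4, 6, 8], self.probes) == 6

    def test_equidistant_tie_lower_coordinate(self):
        probes = pd.DataFrame(
            {"probe_id": ["a", "b"], "chrom": ["17", "17"], "pos": [100, 300]}
        )
        gene = GeneModel(name="G", chrom="17", start=200, end=200 + 1)
        # both 100 away from the single-base gene: lower coordinate wins
        assert gene_copy_number(gene, [2, 6], probes) == 2

    def test_empty_probe_list_raises(self):
        gene = GeneModel(name="G", chrom="17", start=0, end=10)
        with pytest.raises(ValueError, match="empty probe list"):
            gene_copy_number(gene, [], self.probes.iloc[:0])

    def test_wrong_chromosome_raises(self):
        gene = GeneModel(name="G", chrom="5", start=0, end=10)
        with pytest.raises(ValueError, match="chromosome"):
            gene_copy_number(gene, [2, 2, 2, 2], self.probes)


class TestStatusMatrix:
    def _setup(self, **config_overrides):
        config = make_config(**config_overrides)
        dataset, truth = simulate_cohort(config)
        genes = [
            GeneModel(name="IN_AMP", chrom="17", start=900_000, end=1_100_000),
            GeneModel(name="OUT_AMP", chrom="17", start=100_000, end=200_000),
        ]
        expr, ref = simulate_expression(config, truth, genes, probes=dataset.probes)
        statuses = status_matrix(genes, truth.cn, dataset.probes, expr, ref)
        return statuses, truth

    def test_equal_signal_not_overexpressed(self):
        statuses, _ = self._setup(dosage_coupling=0.0)
        out = statuses[statuses["gene"] == "OUT_AMP"]
        np.testing.assert_allclose(out["fold_change"], 1.0)
        assert not out["overexpressed"].any()

    def test_flags_independent(self):
        genes = [GeneModel(name="G", chrom="17", start=0, end=100)]
        probes = pd.DataFrame({"probe_id": ["p1"], "chrom": ["17"], "pos": [50]})
        cn = pd.DataFrame({"S1": [2]}, index=["p1"])
        expr = pd.DataFrame({"S1": [20.0]}, index=pd.Index(["G"], name="gene"))
        ref = pd.Series([10.0], index=["G"])
        statuses = status_matrix(genes, cn, probes, expr, ref)
        row = statuses.iloc[0]
        assert row["overexpressed"] and not row["amplified"]
        assert row["fold_change"] == pytest.approx(2.0)

    def test_full_coupling_amplified_implies_overexpressed(self):
        # CN 6, slope 1, coupling 1: fold change 3 >= 2 for every carrier
        statuses, _ = self._setup(dosage_coupling=1.0)
        amp = statuses[statuses["amplified"]]
        assert len(amp) > 0
        np.testing.assert_allclose(amp["fold_change"], 3.0)
        assert amp["overexpressed"].all()

    def test_probe_level_expression_collapsed(self):
        genes = [GeneModel(name="G", chrom="17", start=0, end=100)]
        probes = pd.DataFrame({"probe_id": ["p1"], "chrom": ["17"], "pos": [50]})
        cn = pd.DataFrame({"S1": [2]}, index=["p1"])
        expr = pd.DataFrame({"S1": [10.0, 30.0]}, index=pd.Index(["G", "G"], name="gene"))
        ref = pd.Series([10.0, 10.0], index=["G", "G"])
        statuses = status_matrix(genes, cn, probes, expr, ref)
        assert statuses["fold_change"].iloc[0] == pytest.approx(2.0)

    def test_non_positive_reference_raises(self):
        genes = [GeneModel(name="G", chrom="17", start=0, end=100)]
        probes = pd.DataFrame({"probe_id": ["p1"], "chrom": ["17"], "pos": [50]})
        cn = pd.DataFrame({"S1": [2]}, index=["p1"])
        expr = pd.DataFrame({"S1": [10.0]}, index=pd.Index(["G"], name="gene"))
        ref = pd.Series([0.0], index=["G"])
        with pytest.raises(ValueError, match="reference signal for gene G"):
            status_matrix(genes, cn, probes, expr, ref)


class TestSummarizeOA:
    @pytest.mark.parametrize("gene,counts", TABLE1.items())
    def test_published_percentages(self, gene, counts):
        a, o, oa, pct = counts
        summary = summarize_oa(gene, expand_counts(gene, a, o, oa, 20))
        assert (summary.a, summary.o, summary.oa) == (a, o, oa)
        assert summary.pct_display == pct

    def test_a_zero_pct_undefined(self):
        summary = summarize_oa("G", expand_counts("G", 0, 5, 0, 20))
        assert summary.pct is None
        assert rank_candidates([summary]) == []

    def test_oa_cannot_exceed_min(self):
        with pytest.raises(ValueError, match="OA"):
            OverAmpSummary(gene="G", a=3, o=5, oa=4)

    def test_counts_from_dataframe_and_dataclasses_agree(self):
        statuses = expand_counts("G", 7, 5, 4, 12)
        as_df = pd.DataFrame([vars(s) for s in statuses])
        assert summarize_oa("G", statuses) == summarize_oa("G", as_df)


class TestRankCandidates:
    def _summaries(self):
        return [OverAmpSummary(gene=g, a=a, o=o, oa=oa) for g, (a, o, oa, _) in TABLE1.items()]

    def test_published_counts_keep_all_eleven(self):
        ranked = rank_candidates(self._summaries(), min_pct=50)
        assert len(ranked) == 11
        assert ranked[0].gene == "SHMT1"
        assert ranked[0].pct_display == 76.5
        assert ranked[-1].gene == "C17orf45"
        assert ranked[-1].pct_display == 50.0
        pcts = [s.pct for s in ranked]
        assert pcts == sorted(pcts, reverse=True)

    def test_all_below_threshold_empty(self):
        summaries = [OverAmpSummary(gene="G1", a=10, o=4, oa=4)]
        assert rank_candidates(summaries, min_pct=50) == []

    def test_tie_alphabetical(self):
        # RICH2 and ALKBH5 tie at 52.9 with equal OA: alphabetical order
        ranked = rank_candidates(self._summaries(), min_pct=50)
        tied = [s.gene for s in ranked if s.pct_display == 52.9]
        assert tied == ["ALKBH5", "RICH2"]

    def test_inclusive_threshold_boundary(self):
        at_fifty = OverAmpSummary(gene="EDGE", a=18, o=10, oa=9)
        assert at_fifty.pct == 50.0
        assert rank_candidates([at_fifty], min_pct=50) == [at_fifty]


class TestPearsonFilter:
    def test_perfect_linearity(self):
        res = pearson_filter([2, 2, 4, 6, 8], [4, 4, 8, 12, 16])
        assert res.r == pytest.approx(1.0)
        assert res.passes

    def test_negative_correlation_fails(self):
        res = pearson_filter([2, 3, 4, 5], [-2, -3, -4, -5])
        assert res.r == pytest.approx(-1.0)
        assert not res.passes

    def test_example_matches_oracle(self):
        cn = [2, 2, 4, 6, 8]
        expr = [1, 2, 2, 5, 7]
        res = pearson_filter(cn, expr)
        assert res.r == pytest.approx(pearson_oracle(cn, expr), abs=1e-12)

    def test_random_vectors_match_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(3, 50))
            x = rng.normal(0, 1, n).tolist()
            y = rng.normal(0, 1, n).tolist()
            res = pearson_filter(x, y)
            assert res.r == pytest.approx(pearson_oracle(x, y), abs=1e-12)
            # t-transform p-value oracle
            t = res.r * math.sqrt((n - 2) / (1 - res.r**2))
            from scipy import stats
            p_oracle = 2 * stats.t.sf(abs(t), n - 2)
            assert res.p == pytest.approx(p_oracle, rel=1e-9)

    def test_constant_vector_flagged_not_raised(self):
        res = pearson_filter([2, 2, 2, 2], [1, 2, 3, 4])
        assert res.constant_input
        assert not res.passes
        assert math.isnan(res.r)

    def test_too_few_points_raises(self):
        with pytest.raises(ValueError, match=">= 3"):
            pearson_filter([1, 2], [1, 2])


class TestTable2Filter:
    def _results(self):
        return [correlation_from_published(g, r, p) for g, (r, p) in TABLE2.items()]

    def test_published_rows_discard_grap_and_alkbh5(self):
        passing, discarded = apply_table2_filter(self._results())
        assert len(passing) == 9
        assert {r.gene for r in discarded} == {"GRAP", "ALKBH5"}

    def test_rasd1_boundary_passes(self):
        res = correlation_from_published("RASD1", 0.49, 0.02)
        assert res.passes

    def test_all_negative_all_discarded(self):
        results = [correlation_from_published(f"G{i}", -0.5, 0.001) for i in range(4)]
        passing, discarded = apply_table2_filter(results)
        assert passing == [] and len(discarded) == 4

    def test_order_preserved(self):
        passing, _ = apply_table2_filter(self._results())
        assert [r.gene for r in passing] == [
            g for g in TABLE2 if g not in ("GRAP", "ALKBH5")
        ]

    def test_strict_min_r_mode(self):
        res = correlation_from_published("RASD1", 0.49, 0.02, min_r=0.5)
        assert not res.passes


class TestCouplingRecovery:
    def test_oa_pct_estimates_coupling(self):
        # per-seed coupling in [0.3, 0.9]: the O/A fraction at the realised A
        # is Binomial(A, coupling)/A; check z-scores behave like one
        zs = []
        rng = np.random.default_rng(2024)
        for seed in range(20):
            coupling = float(rng.uniform(0.3, 0.9))
            config = make_config(
                n_tumours=30, seed=seed, dosage_coupling=coupling,
            )
            dataset, truth = simulate_cohort(config)
            genes = [GeneModel(name="IN_AMP", chrom="17", start=900_000, end=1_100_000)]
            expr, ref = simulate_expression(config, truth, genes, probes=dataset.probes)
            statuses = status_matrix(genes, truth.cn, dataset.probes, expr, ref)
            summary = summarize_oa("IN_AMP", statuses)
            assert summary.a == 30  # penetrance 1.0
            se = math.sqrt(coupling * (1 - coupling) / summary.a)
            zs.append((summary.oa / summary.a - coupling) / se)
        zs = np.abs(zs)
        assert (zs < 4).all()
        assert (zs < 2).mean() >= 0.8
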