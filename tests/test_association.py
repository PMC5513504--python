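import numpy as np
import pandas as pd
import pytest
from scipy import stats

import burstnoise as bn
from burstnoise.association import mh_common_or_from_tables


class TestPairedCorrelation:
    def test_identical_intensity_and_target(self, rng):
        a = rng.normal(size=200)
        b = rng.normal(size=200)
        res = bn.paired_correlation(a, a, b, method="pearson")
        assert res.r_a == pytest.approx(1.0)
        assert res.d == pytest.approx(1.0 - abs(res.r_b))
        assert res.d > 0.8

    def test_random_intensity_gives_small_contrast(self, rng):
        x = rng.normal(size=5000)
        a = rng.normal(size=5000)
        b = rng.normal(size=5000)
        res = bn.paired_correlation(x, a, b)
        assert abs(res.d) < 0.05

    def test_zero_variance_vector_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            bn.paired_correlation([1, 1, 1, 1], [1, 2, 3, 4], [4, 3, 2, 1])

    def test_planted_frequency_coupling_detected(self):
        cfg = bn.SimConfig(
            n_genes=5000, groups=(("E1", 200),), seed=41,
            mark_coupling={"m": bn.MarkCoupling("burst_frequency", 0.6)},
        )
        em, truth = bn.simulate_counts(cfg)
        ann = bn.make_annotation(em.gene_ids)
        bn.simulate_marks(truth, cfg, ann)
        res = bn.paired_correlation(
            truth.mark_intensity["m"],
            truth.genes["burst_frequency"],
            truth.genes["burst_size"],
        )
        assert res.d > 0.3


class TestPermutationTest:
    def test_add_one_rule_floor(self, rng):
        x = np.arange(100.0)
        res = bn.permutation_test(x, x, rng.normal(size=100), n_perm=1000, seed=0)
        assert res.p == pytest.approx(1 / 1001)

    def test_null_p_values_are_uniform(self, rng):
        pvals = []
        for k in range(200):
            x = rng.normal(size=60)
            a = rng.normal(size=60)
            b = rng.normal(size=60)
            pvals.append(bn.permutation_test(x, a, b, n_perm=200, seed=k).p)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_monotone_transform_invariance_with_spearman(self, rng):
        x = rng.uniform(1, 10, 300)
        a = x + rng.normal(0, 2, 300)
        b = rng.normal(size=300)
        p1 = bn.permutation_test(x, a, b, method="spearman", n_perm=300, seed=5)
        p2 = bn.permutation_test(np.exp(x), a, b, method="spearman", n_perm=300, seed=5)
        assert p1.p == p2.p
        assert p1.d == pytest.approx(p2.d)

    def test_nperm_below_one_rejected(self, rng):
        with pytest.raises(ValueError, match="n_perm"):
            bn.permutation_test(
                rng.normal(size=10), rng.normal(size=10), rng.normal(size=10),
                n_perm=0,
            )


class TestPartialCorrelation:
    def test_uncorrelated_control_leaves_r_unchanged(self, rng):
        n = 2000
        x = rng.normal(size=n)
        y = 0.5 * x + rng.normal(0, 0.9, n)
        c = rng.normal(size=n)
        plain = stats.spearmanr(x, y).statistic
        partial = bn.partial_correlation(x, y, c)
        assert partial == pytest.approx(plain, abs=0.02)

    def test_perfect_confounding_gives_zero(self, rng):
        n = 500
        c = rng.normal(size=n)
        x = rng.normal(size=n)
        partial = bn.partial_correlation(x, c, c)  # focal y equals the control
        assert partial == pytest.approx(0.0, abs=1e-6)

    def test_planted_confounder_recovered(self, rng):
        # x and y share a confounder c plus a direct link of known strength
        n = 4000
        c = rng.normal(size=n)
        x = 0.6 * c + rng.normal(0, 0.8, n)
        direct = 0.4
        y = direct * x + 0.5 * c + rng.normal(0, 0.7, n)
        partial = bn.partial_correlation(y, x, c)
        # linear-Gaussian oracle: residual corr = direct*sd_xres / sd_yres
        sd_xres = np.sqrt(0.8**2)
        sd_yres = np.sqrt(direct**2 * 0.8**2 + 0.7**2)
        expected = direct * sd_xres / sd_yres
        assert partial == pytest.approx(expected, abs=0.05)


class TestAxisGroups:
    @staticmethod
    def _table(mean, cv):
        return pd.DataFrame(
            {"mean": mean, "cv": cv},
            index=pd.Index([f"g{i}" for i in range(len(mean))], name="gene_id"),
        )

    def test_square_corners_one_per_group(self):
        # 4 corner points of a centered square: the partition puts exactly
        # one in each group whatever the (degenerate) axis orientation
        log_mean = np.array([1.0, 1.0, -1.0, -1.0] * 3)
        log_cv = np.array([1.0, -1.0, 1.0, -1.0] * 3)
        table = self._table(2.0**log_mean, 2.0**log_cv)
        groups = bn.axis_groups(table)
        assert set(groups["group"].iloc[:4]) == {1, 2, 3, 4}

    def test_group_labels_follow_high_low_semantics(self):
        # anticorrelated cloud (noise falls with expression); genes above the
        # trend are the high-noise side at a given expression
        log_mean = np.array([2.0, 2.0, -2.0, -2.0] * 3)
        log_cv = np.array([-0.5, -1.5, 1.5, 0.5] * 3)
        table = self._table(2.0**log_mean, 2.0**log_cv)
        groups = bn.axis_groups(table)
        assert groups.loc["g0", "group"] == 1  # high expr, above the trend
        assert groups.loc["g1", "group"] == 2  # high expr, below the trend
        assert groups.loc["g2", "group"] == 3  # low expr, above the trend
        assert groups.loc["g3", "group"] == 4  # low expr, below the trend

    def test_on_axis_points_take_low_side(self):
        log_mean = np.array([3.0, -3.0, 1.0, -1.0, 2.0, -2.0, 0.5, -0.5, 1.5, -1.5])
        table = self._table(2.0**log_mean, np.ones(10))  # all on the major axis
        groups = bn.axis_groups(table)
        assert set(groups["major_side"]) == {"low_noise"}

    def test_too_few_genes_rejected(self):
        table = self._table(np.ones(5), np.ones(5))
        with pytest.raises(ValueError, match="10 genes"):
            bn.axis_groups(table)

    def test_size_dominant_genes_sit_on_high_noise_side(self):
        # genes with large burst size carry more noise at a given expression
        cfg = bn.SimConfig(n_genes=3000, groups=(("E1", 200),), seed=42)
        em, truth = bn.simulate_counts(cfg)
        em = bn.filter_detected(em)
        nt = bn.noise_cv(em)
        groups = bn.axis_groups(nt)
        common = groups.index
        high_noise = groups.loc[common, "major_side"] == "high_noise"
        bsize = truth.genes.loc[common, "burst_size"]
        assert bsize[high_noise].median() > bsize[~high_noise].median()

    def test_confident_flag_subset_and_extremes(self, rng):
        n = 400
        log_mean = rng.normal(0, 2, n)
        log_cv = -0.5 * log_mean + rng.normal(0, 0.3, n)
        log_cv[0] += 3.0  # far off the major axis
        table = self._table(2.0**log_mean, 2.0**log_cv)
        groups = bn.axis_groups(table, confidence=True, n_boot=200, seed=1)
        assert groups["confident"].dtype == bool
        assert groups["confident"].sum() < n
        assert groups.loc["g0", "confident"]


class TestUsagePreference:
    def test_independent_mark_has_unit_ratios(self, rng):
        n = 2000
        groups = pd.Series(
            rng.integers(1, 5, n), index=[f"g{i}" for i in range(n)]
        )
        intensity = pd.DataFrame(
            {"m": rng.normal(size=n)}, index=groups.index
        )
        out = bn.usage_preference(groups, intensity)
        assert out["ratio"].between(0.75, 1.35).all()
        assert out["p"].min() > 1e-4

    def test_extreme_enrichment(self):
        n = 400
        genes = [f"g{i}" for i in range(n)]
        groups = pd.Series([2] * 200 + [1] * 200, index=genes)
        intensity = pd.DataFrame(
            {"m": [1.0] * 200 + [0.0] * 200}, index=genes
        )
        out = bn.usage_preference(groups, intensity)
        row = out[(out["mark"] == "m") & (out["group"] == 2)].iloc[0]
        assert np.isinf(row["ratio"])
        assert row["n_high"] == 200 and row["n_low"] == 0
        assert row["p"] < 1e-10

    def test_median_ties_go_low_on_odd_counts(self):
        genes = ["a", "b", "c"]
        groups = pd.Series([1, 1, 2], index=genes)
        intensity = pd.DataFrame({"m": [1.0, 2.0, 3.0]}, index=genes)
        out = bn.usage_preference(groups, intensity)
        row = out[(out["mark"] == "m") & (out["group"] == 1)].iloc[0]
        assert (row["n_high"], row["n_low"]) == (0, 2)  # the median value is low


class TestMantelHaenszel:
    def test_hand_worked_common_or(self):
        tables = [np.array([[10, 5], [5, 10]])] * 2
        res = mh_common_or_from_tables(tables)
        # MH sums: (10*10/30)*2 / ((5*5/30)*2) = 4
        assert res.common_or == pytest.approx(4.0)
        assert res.ci_low < 4.0 < res.ci_high

    def test_all_equal_cells_give_unit_or(self):
        tables = [np.array([[7, 7], [7, 7]])] * 3
        assert mh_common_or_from_tables(tables).common_or == pytest.approx(1.0)

    def test_single_stratum_equals_plain_or(self):
        t = np.array([[12, 4], [6, 9]])
        res = mh_common_or_from_tables([t])
        assert res.common_or == pytest.approx((12 * 9) / (4 * 6))

    def test_empty_margin_stratum_dropped(self, caplog):
        tables = [np.array([[10, 5], [5, 10]]), np.array([[0, 0], [5, 10]])]
        with caplog.at_level("INFO", logger="burstnoise.association"):
            res = mh_common_or_from_tables(tables)
        assert res.n_strata_used == 1
        assert res.common_or == pytest.approx(4.0)

    def test_stratification_removes_expression_confounding(self, rng):
        # plant a within-bin OR of exactly 2 while both the marginal
        # sensitivity rate and the intensity rise with expression
        n_bins, per_bin = 10, 400
        rows = []
        for b in range(n_bins):
            base = 0.1 + 0.06 * b  # P(sensitive | low intensity) rises with expression
            odds_high = 2.0 * base / (1 - base)
            p_high = odds_high / (1 + odds_high)
            for j in range(per_bin):
                high = j < per_bin // 2
                rows.append(
                    (
                        b + rng.random(),  # expression: deciles == bins
                        b * 10.0 + (1.0 if high else 0.0),
                        bool(rng.random() < (p_high if high else base)),
                    )
                )
        df = pd.DataFrame(rows, columns=["expression", "intensity", "sensitive"])
        strat = bn.mh_common_or(df, n_bins=10)
        pooled = bn.mh_common_or(df, n_bins=1)
        assert strat.common_or == pytest.approx(2.0, abs=0.45)
        assert pooled.common_or > strat.common_or + 0.4  # biased away by confounding


class TestRelativeIntensityRatio:
    def test_gene_matching_control_median_gets_unit_ratio(self, rng):
        genes = [f"g{i}" for i in range(120)]
        num = pd.Series(2.0, index=genes)
        den = pd.Series(1.0, index=genes)
        expr = pd.Series(rng.lognormal(0, 1, 120), index=genes)
        out = bn.relative_intensity_ratio(
            ["g0"], num, den, expr, control_genes=genes[1:], n_controls=100
        )
        assert out["g0"] == pytest.approx(1.0)

    def test_invariant_to_uniform_numerator_scaling(self, rng):
        genes = [f"g{i}" for i in range(150)]
        num = pd.Series(rng.uniform(1, 3, 150), index=genes)
        den = pd.Series(rng.uniform(1, 3, 150), index=genes)
        expr = pd.Series(rng.lognormal(0, 1, 150), index=genes)
        r1 = bn.relative_intensity_ratio(genes[:10], num, den, expr, genes[10:])
        r2 = bn.relative_intensity_ratio(genes[:10], 2 * num, den, expr, genes[10:])
        pd.testing.assert_series_equal(r1, r2)

    def test_planted_twofold_pathway_ratio_recovered(self, rng):
        n = 300
        genes = [f"g{i}" for i in range(n)]
        expr = pd.Series(rng.lognormal(0, 1, n), index=genes)
        den = pd.Series(rng.uniform(0.5, 2, n), index=genes)
        num = den * rng.lognormal(0, 0.2, n)
        pathway = genes[:30]
        num[pathway] *= 2.0  # plant a 2x higher ratio in the pathway
        out = bn.relative_intensity_ratio(pathway, num, den, expr, genes[30:])
        assert np.median(out) == pytest.approx(2.0, rel=0.15)

    def test_zero_denominator_gene_excluded(self, rng):
        genes = [f"g{i}" for i in range(50)]
        num = pd.Series(1.0, index=genes)
        den = pd.Series(1.0, index=genes)
        den["g0"] = 0.0
        expr = pd.Series(np.linspace(1, 2, 50), index=genes)
        out = bn.relative_intensity_ratio(
            ["g0", "g1"], num, den, expr, genes[2:], n_controls=10
        )
        assert "g0" not in out.index and "g1" in out.index

    def test_small_control_group_warns_and_uses_all(self, caplog):
        genes = [f"g{i}" for i in range(10)]
        num = pd.Series(1.0, index=genes)
        den = pd.Series(1.0, index=genes)
        expr = pd.Series(np.linspace(1, 2, 10), index=genes)
        with caplog.at_level("WARNING", logger="burstnoise.association"):
            bn.relative_intensity_ratio(["g0"], num, den, expr, genes[1:], n_controls=100)
        assert any("n_controls" in m for m in caplog.messages)


class TestTwoGroupNoiseTest:
    def test_shifted_distributions_detected(self, rng):
        cv = pd.Series(
            np.exp(np.concatenate([rng.normal(0, 1, 500), rng.normal(1, 1, 500)]))
        )
        label = pd.Series([False] * 500 + [True] * 500)
        _, p = bn.two_group_noise_test(cv, label)
        assert p < 0.001

    def test_identical_distributions_null(self, rng):
        pvals = []
        for _ in range(50):
            cv = pd.Series(np.exp(rng.normal(0, 1, 200)))
            label = pd.Series(rng.random(200) < 0.5)
            pvals.append(bn.two_group_noise_test(cv, label)[1])
        assert min(pvals) > 1e-4 or np.mean(np.array(pvals) < 0.05) < 0.2

    def test_empty_class_rejected(self):
        cv = pd.Series([1.0, 2.0])
        with pytest.raises(ValueError, match="non-empty"):
            bn.two_group_noise_test(cv, pd.Series([True, True]))
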