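"""Marker QC statistics: germination, allele classes, FPR/FNR, utility,
Kruskal-Wallis effects, single-marker regression and the CRD ANOVA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from kaspanel import qc
from kaspanel.datamodel import HET, HOM_ALT, HOM_REF, MISSING, ValidationError
from kaspanel.io import load_table3


class TestGermination:
    @pytest.mark.parametrize(
        "emerged,planted,expected",
        [(1, 12, 8.33), (0, 12, 0.0), (11, 12, 91.67), (3, 18, 16.67)],
    )
    def test_published_grid_values(self, emerged, planted, expected):
        assert qc.germination_percent(emerged, planted) == expected

    def test_bad_inputs(self):
        with pytest.raises(ValidationError):
            qc.germination_percent(1, 0)
        with pytest.raises(ValidationError):
            qc.germination_percent(13, 12)


class TestAlleleClassSummary:
    def test_counts_partition_and_frequencies(self):
        calls = pd.Series(
            [HOM_REF] * 156 + [HOM_ALT] * 166 + [HET] * 40 + [MISSING] * 12
        )
        s = qc.allele_class_summary(calls)
        assert s["n_tested"] == 374
        assert s["n_negative"] + s["n_positive"] + s["n_het"] + s["n_missing"] == 374
        assert s["freq_negative"] == 41.7  # 156/374
        assert s["freq_positive"] == 44.4  # 166/374

    def test_all_het_flags_empty_classes(self):
        calls = pd.Series([HET] * 20)
        pheno = pd.DataFrame({"t": np.arange(20.0)})
        s = qc.allele_class_summary(calls, pheno, ["t"])
        assert s["freq_negative"] == 0.0 and s["freq_positive"] == 0.0
        assert np.isnan(s["mean_negative"]["t"]) and np.isnan(s["mean_positive"]["t"])
        assert "empty_negative_class" in s["flags"]

    def test_bundled_panel_frequencies_recompute(self):
        """Class count / n_tested reproduces every printed percentage within
        0.1 except rows flagged as internally inconsistent in the source."""
        t = load_table3()
        for row in t.itertuples(index=False):
            flags = row.provenance_flags
            checks = []
            if "pctA_inconsistent_with_counts" not in flags:
                checks.append((row.n_negative_A, row.n_tested_A, row.pct_negative_A))
            if "pctA_pos_inconsistent" not in flags and "pctA_inconsistent_with_counts" not in flags:
                checks.append((row.n_positive_A, row.n_tested_A, row.pct_positive_A))
            if "pctB_inconsistent_with_counts" not in flags:
                checks.append((row.n_negative_B, row.n_tested_B, row.pct_negative_B))
            if "pctB_pos_inconsistent" not in flags:
                checks.append((row.n_positive_B, row.n_tested_B, row.pct_positive_B))
            for count, n, printed in checks:
                assert abs(round(100 * count / n, 1) - printed) <= 0.1 + 1e-9, row.marker_id


class TestErrorRates:
    def test_zero_error_gives_zero_rates(self):
        truth = pd.Series([HOM_REF] * 50 + [HET] * 30 + [HOM_ALT] * 20)
        assert qc.false_positive_rate(truth, truth) == 0.0
        assert qc.false_negative_rate(truth, truth) == 0.0

    def test_all_flipped_gives_one(self):
        truth = pd.Series([HOM_REF] * 40 + [HOM_ALT] * 40)
        calls = pd.Series([HOM_ALT] * 40 + [HOM_REF] * 40)
        assert qc.false_positive_rate(calls, truth) == 1.0
        assert qc.false_negative_rate(calls, truth) == 1.0

    def test_undefined_without_truth_class(self):
        truth = pd.Series([HOM_ALT] * 10)
        calls = truth.copy()
        assert np.isnan(qc.false_positive_rate(calls, truth))

    def test_missing_calls_count_by_default_but_can_be_excluded(self):
        truth = pd.Series([HOM_REF] * 10)
        calls = pd.Series([HOM_REF] * 8 + [MISSING] * 2)
        assert qc.false_positive_rate(calls, truth) == pytest.approx(0.2)
        assert qc.false_positive_rate(calls, truth, missing_counts=False) == 0.0

    @pytest.mark.parametrize("rate", [0.01, 0.05, 0.10])
    @pytest.mark.parametrize("n", [1000, 10_000])
    def test_binomial_recovery_grid(self, rate, n):
        """Injected flip rates are recovered unbiased within 3 sigma."""
        from kaspanel import simulate as sim

        rng = np.random.default_rng(int(rate * 1000) + n)
        truth = pd.DataFrame(
            {"K_1": rng.choice([HOM_REF, HET, HOM_ALT], size=n, p=[0.4, 0.3, 0.3])}
        )
        calls, _ = sim.inject_assay_error(truth, rate, rate, 0.0, rng)
        fpr = qc.false_positive_rate(calls["K_1"], truth["K_1"])
        fnr = qc.false_negative_rate(calls["K_1"], truth["K_1"])
        n_recip = (truth["K_1"] == HOM_REF).sum()
        n_carrier = n - n_recip
        assert abs(fpr - rate) <= 3 * np.sqrt(rate * (1 - rate) / n_recip)
        assert abs(fnr - rate) <= 3 * np.sqrt(rate * (1 - rate) / n_carrier)


class TestUtility:
    def test_opposite_homozygotes_only(self):
        parents = pd.Series(
            {"D": HOM_ALT, "R1": HOM_REF, "R2": HOM_REF, "R3": HET, "R4": MISSING, "R5": HOM_ALT}
        )
        u = qc.kasp_utility(parents, "D", ["R1", "R2", "R3", "R4", "R5"])
        assert u == frozenset({"R1", "R2"})

    def test_het_donor_has_no_utility(self):
        parents = pd.Series({"D": HET, "R1": HOM_REF})
        assert qc.kasp_utility(parents, "D", ["R1"]) == frozenset()


class TestKruskalWallis:
    def test_hand_computed_h_and_permutation_p(self):
        calls = pd.Series([HOM_REF] * 3 + [HOM_ALT] * 3)
        pheno = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        H, p, sig = qc.kruskal_wallis_effect(calls, pheno)
        assert H == pytest.approx(3.857, abs=1e-3)
        perm_p = qc.kruskal_wallis_permutation_p(
            [pheno[:3].to_numpy(), pheno[3:].to_numpy()]
        )
        assert perm_p == pytest.approx(0.100, abs=1e-9)

    def test_identical_groups_h_zero(self):
        calls = pd.Series([HOM_REF] * 4 + [HOM_ALT] * 4)
        pheno = pd.Series([5.0] * 8)
        H, p, sig = qc.kruskal_wallis_effect(calls, pheno)
        assert (H, p, sig) == (0.0, 1.0, "ns")

    @pytest.mark.parametrize(
        "p,expected",
        [(0.2, "ns"), (0.04, "*"), (0.004, "**"), (0.0004, "***")],
    )
    def test_significance_tiers(self, p, expected):
        assert qc.significance_tier(p) == expected

    def test_h_invariant_under_monotone_transform(self, rng):
        calls = pd.Series(rng.choice([HOM_REF, HOM_ALT], size=30))
        pheno = pd.Series(rng.normal(size=30))
        H1, _, _ = qc.kruskal_wallis_effect(calls, pheno)
        H2, _, _ = qc.kruskal_wallis_effect(calls, np.exp(pheno) + 3)
        assert H1 == pytest.approx(H2, abs=1e-9)

    def test_chisquare_p_close_to_permutation_p_small_n(self, rng):
        """For two tie-free groups of <= 10 the chi-square p tracks the exact
        permutation p within 0.02 wherever a significance call is at stake
        (p < 0.1) and within 0.06 everywhere: checked over the entire exact
        null distribution of H, and spot-checked through the permutation
        routine on random data."""
        from itertools import combinations

        n1, n2 = 7, 8
        N = n1 + n2
        ranks = np.arange(1, N + 1)
        Hs = []
        for idx in combinations(range(N), n1):
            r1 = ranks[list(idx)].sum()
            r2 = ranks.sum() - r1
            Hs.append(12 / (N * (N + 1)) * (r1**2 / n1 + r2**2 / n2) - 3 * (N + 1))
        Hs = np.array(Hs)
        for h in np.unique(Hs.round(10)):
            exact = (Hs >= h - 1e-9).mean()
            approx = stats.chi2.sf(h, 1)
            assert abs(exact - approx) < 0.06
            if min(exact, approx) < 0.1:
                assert abs(exact - approx) < 0.02
        a = rng.normal(1.2, 1, size=n1)
        b = rng.normal(0.0, 1, size=n2)
        _, p = stats.kruskal(a, b)
        perm = qc.kruskal_wallis_permutation_p([a, b])  # same enumeration path
        assert abs(p - perm) < 0.06

    def test_het_group_optional(self):
        calls = pd.Series([HOM_REF] * 5 + [HET] * 5 + [HOM_ALT] * 5)
        pheno = pd.Series(np.arange(15.0))
        H2, _, _ = qc.kruskal_wallis_effect(calls, pheno, include_het=False)
        H3, _, _ = qc.kruskal_wallis_effect(calls, pheno, include_het=True)
        assert H3 != H2


class TestSingleMarker:
    def test_perfectly_linear_r2_one(self):
        calls = pd.Series([0, 1, 2, 0, 1, 2, 0, 1, 2])
        pheno = pd.Series(calls * 3.0 + 1.0)
        r2, p = qc.single_marker_analysis(calls, pheno)
        assert r2 == pytest.approx(1.0)
        assert p < 1e-6

    def test_r2_equals_squared_pearson(self, rng):
        calls = pd.Series(rng.choice([0, 1, 2], size=60))
        pheno = pd.Series(rng.normal(size=60) + 0.5 * calls)
        r2, _ = qc.single_marker_analysis(calls, pheno)
        r = np.corrcoef(calls, pheno)[0, 1]
        assert r2 == pytest.approx(r**2, abs=1e-12)

    def test_null_p_values_are_uniform(self, rng):
        """Permuting genotype against phenotype gives uniform p (KS test)."""
        calls = pd.Series(np.repeat([0, 1, 2], 10))
        pheno = pd.Series(rng.normal(size=30))
        ps = []
        for _ in range(2000):
            perm = pd.Series(rng.permutation(calls.to_numpy()))
            _, p = qc.single_marker_analysis(perm, pheno)
            ps.append(p)
        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.01


class TestAnovaCRD:
    def test_zero_error_variance_flag(self):
        out = qc.anova_crd({"g1": [10, 10, 10], "g2": [20, 20, 20]})
        assert out["mse"] == 0.0 and np.isinf(out["F"])
        assert out["flag"] == "zero_error_variance"

    def test_all_equal_gives_f_zero_p_one(self):
        out = qc.anova_crd({"g1": [7, 7], "g2": [7, 7]})
        assert out["ss_treatment"] == 0.0 and out["F"] == 0.0 and out["p"] == 1.0

    def test_cv_percent_closed_form(self, rng):
        """sigma=2 around mean 20 -> CV ~= 10%."""
        obs = {f"g{i}": rng.normal(20, 2, size=50) for i in range(10)}
        out = qc.anova_crd(obs)
        assert out["cv_pct"] == pytest.approx(10.0, abs=1.5)

    def test_singleton_genotype_dropped(self):
        out = qc.anova_crd({"g1": [1.0], "g2": [3.0, 4.0], "g3": [5.0, 6.0]})
        assert out["df_treatment"] == 1  # g1 dropped, two groups remain

    def test_matches_scipy_f_oneway(self, rng):
        groups = {f"g{i}": rng.normal(i, 1, size=12) for i in range(4)}
        out = qc.anova_crd(groups)
        F, p = stats.f_oneway(*groups.values())
        assert out["F"] == pytest.approx(F)
        assert out["p"] == pytest.approx(p)
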