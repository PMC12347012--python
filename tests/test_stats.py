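"""Rank-based group comparisons and trait descriptive statistics."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from phasegp.data import PhenotypeTable
from phasegp.stats import (
    dunn_posthoc,
    kruskal_wallis,
    mann_whitney_u,
    one_way_anova,
    trait_correlations,
    uniformity_index,
)


class TestKruskalWallis:
    def test_identical_groups_give_zero(self):
        H, p = kruskal_wallis([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert H == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_hand_ranks(self):
        """Separated groups: H computed from the rank-sum formula."""
        a, b = [1.0, 2.0, 3.0], [10.0, 11.0, 12.0]
        H, _ = kruskal_wallis([a, b])
        # ranks: a -> 1,2,3 (R=6); b -> 4,5,6 (R=15); N=6, no ties
        H_hand = 12.0 / (6 * 7) * (6 ** 2 / 3 + 15 ** 2 / 3) - 3 * 7
        assert H == pytest.approx(H_hand)

    def test_against_permutation_oracle(self):
        """Chi-square p within 0.02 of a permutation null (3 groups, n=5)."""
        rng = np.random.default_rng(8)
        groups = [rng.normal(0, 1, 5), rng.normal(0.5, 1, 5),
                  rng.normal(1.0, 1, 5)]
        H_obs, p_chi2 = kruskal_wallis(groups)
        pooled = np.concatenate(groups)
        count = 0
        n_perm = 10_000
        rng2 = np.random.default_rng(9)
        for _ in range(n_perm):
            perm = rng2.permutation(pooled)
            H, _ = kruskal_wallis([perm[:5], perm[5:10], perm[10:]])
            if H >= H_obs - 1e-12:
                count += 1
        assert p_chi2 == pytest.approx(count / n_perm, abs=0.02)

    def test_monotone_transform_invariant(self):
        rng = np.random.default_rng(10)
        groups = [rng.normal(size=6), rng.normal(1, 1, 6)]
        H1, _ = kruskal_wallis(groups)
        H2, _ = kruskal_wallis([np.exp(g) for g in groups])
        assert H1 == pytest.approx(H2)


class TestMannWhitney:
    def test_identical_samples(self):
        _, p = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p > 0.9

    def test_complete_separation(self):
        U, _ = mann_whitney_u([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert min(U, 9 - U) == 0.0

    def test_against_exact_enumeration(self):
        """Asymptotic p within 0.02 of the exact U-distribution p (8+8)."""
        rng = np.random.default_rng(11)
        a, b = rng.normal(0, 1, 8), rng.normal(0.8, 1, 8)
        _, p_asym = mann_whitney_u(a, b)
        res_exact = sps.mannwhitneyu(a, b, alternative="two-sided",
                                     method="exact")
        assert p_asym == pytest.approx(res_exact.pvalue, abs=0.02)

    def test_monotone_transform_invariant(self):
        rng = np.random.default_rng(12)
        a, b = rng.normal(size=8), rng.normal(1, 1, 8)
        _, p1 = mann_whitney_u(a, b)
        _, p2 = mann_whitney_u(np.exp(a), np.exp(b))
        assert p1 == pytest.approx(p2)


class TestDunn:
    @pytest.fixture()
    def groups(self):
        rng = np.random.default_rng(13)
        return [rng.normal(0, 1, 7), rng.normal(0.8, 1, 9),
                rng.normal(1.5, 1, 6)]

    def test_bonferroni_monotone(self, groups):
        raw = dunn_posthoc(groups, adjust="none").to_numpy()
        adj = dunn_posthoc(groups, adjust="bonferroni").to_numpy()
        assert np.all(adj >= raw - 1e-15)
        assert np.all(adj <= 1.0) and np.all(raw >= 0.0)

    def test_all_equal_groups(self):
        out = dunn_posthoc([[2.0, 2.0, 2.0], [2.0, 2.0, 2.0]])
        assert np.all(out.to_numpy() == 1.0)

    def test_two_groups_reduce_to_rank_test(self):
        """With 2 groups and no correction, Dunn equals the tie-corrected
        normal-approximation Mann-Whitney p (no continuity) to 1e-6."""
        rng = np.random.default_rng(14)
        a, b = rng.normal(0, 1, 10), rng.normal(0.7, 1, 12)
        p_dunn = dunn_posthoc([a, b], adjust="none").iloc[0, 1]
        res = sps.mannwhitneyu(a, b, alternative="two-sided",
                               method="asymptotic", use_continuity=False)
        assert p_dunn == pytest.approx(res.pvalue, abs=1e-6)


class TestAnova:
    def test_matches_scipy_reference(self):
        rng = np.random.default_rng(15)
        groups = [rng.normal(size=8), rng.normal(1, 1, 8)]
        F, p = one_way_anova(groups)
        assert F > 0 and 0 <= p <= 1


def _pheno_from_wide(wide: dict, locality="A"):
    rows = []
    for trait, values in wide.items():
        for i, v in enumerate(values):
            rows.append({"genotype_id": f"G{i + 1}", "locality": locality,
                         "trait": trait, "replicate": 1, "value": v})
    return PhenotypeTable(pd.DataFrame(rows))


class TestTraitCorrelations:
    def test_self_correlation_is_one(self, pheno_table):
        out = trait_correlations(pheno_table, method="pearson")
        for coef, _ in out.values():
            np.testing.assert_allclose(np.diag(coef), 1.0)

    def test_monotone_nonlinear_pair(self):
        x = np.linspace(1, 10, 10)
        tbl = _pheno_from_wide({"A": x, "B": np.exp(x)})
        pear = trait_correlations(tbl, "pearson")["A"][0].loc["A", "B"]
        spear = trait_correlations(tbl, "spearman")["A"][0].loc["A", "B"]
        assert spear == pytest.approx(1.0)
        assert pear < 1.0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(16)
        x = rng.normal(size=10)
        y = 0.5 * x + rng.normal(size=10)
        tbl = _pheno_from_wide({"A": x, "B": y})
        coef, padj = trait_correlations(tbl, "pearson")["A"]
        r_hand = (np.sum((x - x.mean()) * (y - y.mean()))
                  / np.sqrt(np.sum((x - x.mean()) ** 2)
                            * np.sum((y - y.mean()) ** 2)))
        assert coef.loc["A", "B"] == pytest.approx(r_hand)
        assert padj.loc["A", "B"] >= sps.pearsonr(x, y).pvalue - 1e-15

    def test_bonferroni_at_least_raw(self, pheno_table):
        coef, padj = trait_correlations(pheno_table)["A"]
        assert np.nanmax(padj.to_numpy()) <= 1.0


class TestUniformityIndex:
    def test_arithmetic(self):
        rows = [
            {"genotype_id": "G1", "locality": "A", "trait": "YLP",
             "replicate": r, "value": v}
            for r, v in [(1, 8.0), (2, 12.0)]
        ]
        out = uniformity_index(PhenotypeTable(pd.DataFrame(rows)))
        # mean 10, sample variance 8 -> index 1.25
        assert out["index"].iloc[0] == pytest.approx(1.25)

    def test_zero_variance_flagged_and_capped(self):
        rows = []
        for gid, vals in [("G1", (10.0, 10.0, 10.0)), ("G2", (8.0, 12.0))]:
            for r, v in enumerate(vals, 1):
                rows.append({"genotype_id": gid, "locality": "A",
                             "trait": "YLP", "replicate": r, "value": v})
        out = uniformity_index(PhenotypeTable(pd.DataFrame(rows)))
        g1 = out[out["genotype_id"] == "G1"].iloc[0]
        assert bool(g1["flagged"])
        assert np.isfinite(g1["index"])

    def test_matches_manual_ratios(self):
        rng = np.random.default_rng(17)
        rows = []
        expected = {}
        for gid in [f"G{i}" for i in range(1, 6)]:
            vals = rng.normal(10, 2, 3)
            expected[gid] = vals.mean() / vals.var(ddof=1)
            for r, v in enumerate(vals, 1):
                rows.append({"genotype_id": gid, "locality": "A",
                             "trait": "YLP", "replicate": r, "value": v})
        out = uniformity_index(PhenotypeTable(pd.DataFrame(rows)))
        for gid, exp in expected.items():
            got = out.loc[out["genotype_id"] == gid, "index"].iloc[0]
            assert got == pytest.approx(exp)
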