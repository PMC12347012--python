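"""SNP-chip design: beta ranking, saturation, plateau and overlap algebra."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from phasegp.chip import (
    ChipPanel,
    SaturationCurve,
    make_panel,
    overlap_summary,
    rank_markers,
    saturation_curve,
    select_plateau,
)
from phasegp.models import ModelConfig, PosteriorSummary, fit


def summary_with_beta(beta):
    beta = np.asarray(beta, dtype=float)
    return PosteriorSummary(model="BayesC", mu=0.0, sigma2_e=1.0,
                            sigma2_a=1.0, gebv=np.zeros(3), beta=beta)


class TestRankMarkers:
    def test_orders_by_absolute_effect(self):
        order = rank_markers(summary_with_beta([0.5, -0.9, 0.1]))
        assert order == [1, 0, 2]

    def test_equal_effects_keep_genome_order(self):
        order = rank_markers(summary_with_beta([0.3, 0.3, 0.3, 0.3]))
        assert order == [0, 1, 2, 3]

    def test_matches_brute_force_sort(self):
        rng = np.random.default_rng(0)
        beta = rng.standard_normal(100)
        order = rank_markers(summary_with_beta(beta))
        top10 = set(order[:10])
        expected = set(np.argsort(-np.abs(beta))[:10])
        assert top10 == expected

    def test_rkhs_unsupported(self):
        s = PosteriorSummary(model="RKHS", mu=0, sigma2_e=1, sigma2_a=1,
                             gebv=np.zeros(3), beta=None)
        with pytest.raises(ValueError, match="no marker effects"):
            rank_markers(s)


@pytest.fixture(scope="module")
def curve(trait_sim):
    _, X, y, _ = trait_sim
    cfg = ModelConfig(model="BayesC", n_iter=600, burn_in=150, thin=3)
    return saturation_curve(X, y, cfg, grid=(25, 100, 600),
                            seeds=(0, 1), n_folds=4), X, y, cfg


class TestSaturation:
    def test_full_size_matches_plain_cv(self, curve):
        from phasegp.evaluate import cross_validate
        sat, X, y, cfg = curve
        full = sat.records[(sat.records["size"] == 600)
                           & (sat.records["seed"] == 0)]
        cfg0 = ModelConfig(**{**cfg.__dict__, "seed": 0})
        cv = cross_validate(X, y, cfg0, n_folds=4, seed=0)
        np.testing.assert_allclose(np.sort(full["r_y"].to_numpy()),
                                   np.sort(cv.folds["r_y"].to_numpy()),
                                   atol=1e-10)

    def test_min_mean_max_consistent(self, curve):
        sat = curve[0]
        per = sat.per_size()
        assert (per["min"] <= per["mean"]).all()
        assert (per["mean"] <= per["max"]).all()

    def test_nested_subsets_within_seed(self, trait_sim):
        geno, X, y, _ = trait_sim
        cfg = ModelConfig(model="BayesC", n_iter=600, burn_in=150, seed=4)
        summ = fit(X, y, cfg)
        small = set(make_panel(summ, geno, "T", "L", size=50).markers)
        large = set(make_panel(summ, geno, "T", "L", size=200).markers)
        assert small <= large


class TestPlateau:
    def _curve(self, means):
        rows = [{"size": s, "seed": 0, "fold": 0, "r_y": m}
                for s, m in means.items()]
        return SaturationCurve(grid=tuple(sorted(means)),
                               records=pd.DataFrame(rows))

    def test_flat_curve_smallest(self):
        c = self._curve({25: 0.7, 100: 0.7, 500: 0.7})
        assert select_plateau(c) == 25

    def test_strictly_increasing_delta_zero(self):
        c = self._curve({25: 0.1, 100: 0.5, 500: 0.9})
        assert select_plateau(c, delta=0.0) == 500

    def test_injected_plateau_at_500(self):
        c = self._curve({25: 0.30, 100: 0.50, 200: 0.62, 500: 0.795,
                         1000: 0.80, 5000: 0.81})
        assert select_plateau(c, delta=0.02) == 500


def random_panels(rng, k, size=30, universe=200):
    panels = []
    for i in range(k):
        ids = rng.choice(universe, size=size, replace=False)
        panels.append(ChipPanel("T", f"L{i}",
                                [f"m{j}" for j in ids],
                                np.sort(rng.random(size))[::-1]))
    return panels


class TestOverlap:
    def test_disjoint_panels(self):
        panels = [
            ChipPanel("T", f"L{i}", [f"m{i}_{j}" for j in range(500)],
                      np.linspace(1, 0.5, 500))
            for i in range(3)
        ]
        rep = overlap_summary(panels)
        assert rep["union_size"] == 1500
        assert rep["shared_in_2plus"] == 0
        assert rep["shared_in_2plus_pct"] == 0.0

    def test_identical_panels(self):
        base = [f"m{j}" for j in range(500)]
        panels = [ChipPanel("T", f"L{i}", base, np.linspace(1, 0.5, 500))
                  for i in range(3)]
        rep = overlap_summary(panels)
        assert rep["union_size"] == 500
        assert rep["shared_in_2plus_pct"] == pytest.approx(100.0)
        assert rep["in_all"] == 500

    def test_inclusion_exclusion_on_random_panels(self):
        """Counts agree with brute-force enumeration over 5 random panels."""
        rng = np.random.default_rng(1)
        panels = random_panels(rng, 5)
        rep = overlap_summary(panels)
        sets = [set(p.markers) for p in panels]
        universe = set().union(*sets)
        counts = {m: sum(m in s for s in sets) for m in universe}
        assert rep["union_size"] == len(universe)
        assert rep["shared_in_2plus"] == sum(c >= 2 for c in counts.values())
        assert rep["in_all"] == sum(c == len(sets) for c in counts.values())
        tot_exclusive = sum(rep["exclusive_counts"].values())
        assert tot_exclusive == sum(c == 1 for c in counts.values())
        for (i, j) in combinations(range(5), 2):
            key = f"{panels[i].trait}@{panels[i].locality} & " \
                  f"{panels[j].trait}@{panels[j].locality}"
            assert rep["pairwise_intersections"][key] == len(sets[i] & sets[j])

    def test_needs_two_panels(self):
        rng = np.random.default_rng(2)
        with pytest.raises(ValueError):
            overlap_summary(random_panels(rng, 1))


class TestChipPanelInvariants:
    def test_scores_must_be_sorted(self):
        with pytest.raises(ValueError, match="non-increasing"):
            ChipPanel("T", "L", ["a", "b"], [0.1, 0.5])

    def test_duplicate_markers_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            ChipPanel("T", "L", ["a", "a"], [0.5, 0.1])
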