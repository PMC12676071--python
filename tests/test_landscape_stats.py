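"""Landscapes, group comparisons and allele stacking."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from gametecross import (
    MarkerMap,
    allele_stacking,
    build_landscape,
    compare_landscapes,
    group_effects,
)
from gametecross.crossover import events_to_frame
from gametecross.landscape_stats import Landscape


def _map1(length_mb=800):
    return MarkerMap(
        pd.DataFrame({"marker_id": ["m"], "chromosome": ["1R"], "position_bp": [1]}),
        {"1R": int(length_mb * 1e6)},
    )


def _events(positions, chrom="1R", nucleus="n1"):
    rows = [
        {
            "individual_id": "i1",
            "nucleus_id": nucleus,
            "chromosome": chrom,
            "position_rel": p,
            "resolution": 0,
            "left_window": int(p * 10) - 1,
            "right_window": int(p * 10),
        }
        for p in positions
    ]
    return pd.DataFrame(rows, columns=events_to_frame([]).columns.tolist())


class TestBuildLandscape:
    def test_frequency_and_rate_arithmetic(self):
        # 10 events in one 80-Mb window of an 800-Mb chromosome, 100 gametes
        ev = pd.concat([_events([0.45], nucleus=f"n{k}") for k in range(10)])
        ls = build_landscape(ev, n_gametes=100, marker_map=_map1(800))
        w4 = ls.table.set_index("window").loc[4]
        assert w4["frequency"] == pytest.approx(0.1)
        assert w4["rate_cm_per_mb"] == pytest.approx(0.1 * 100 / 80)

    def test_zero_events_all_zero(self):
        ls = build_landscape(_events([]), 50, _map1())
        assert (ls.table["n_events"] == 0).all()
        assert ls.genome_wide_rate == 0.0

    def test_zero_gametes_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            build_landscape(_events([]), 0, _map1())

    def test_genome_wide_rate_consistency(self, small_results):
        """Summed window frequencies reproduce mean crossovers per nucleus."""
        ls = small_results.landscape()
        mean_per_nucleus = small_results.mean_co_per_nucleus
        assert ls.genome_wide_rate == pytest.approx(
            mean_per_nucleus * 100 / ls.genome_mb, rel=1e-12
        )

    def test_uniform_positions_give_flat_landscape(self, rng):
        """Crossovers placed uniformly yield window counts compatible with a
        flat profile (chi-square goodness of fit, p > 0.01)."""
        pos = rng.uniform(0.1, 0.9, size=4000)  # detectable range only
        ev = pd.concat([_events([p], nucleus=f"n{k}") for k, p in enumerate(pos)])
        ls = build_landscape(ev, len(pos), _map1())
        counts = ls.table.set_index("window")["n_events"].loc[1:8]  # fully covered windows
        _, p = sps.chisquare(counts)
        assert p > 0.01


class TestCompareLandscapes:
    def test_identical_landscapes(self, small_results):
        ls = small_results.landscape()
        cmp = compare_landscapes(ls, ls)
        assert cmp.pearson_r == pytest.approx(1.0)
        assert np.allclose(cmp.per_window["p_fdr"], 1.0)
        assert cmp.n_significant == 0

    def test_reversed_monotone_profile_anticorrelates(self):
        mm = _map1()
        freqs = np.linspace(0.05, 0.5, 10)
        base = build_landscape(_events([]), 100, mm).table.copy()
        a = base.copy()
        a["frequency"] = freqs
        a["n_recombinant"] = (freqs * 100).astype(int)
        b = base.copy()
        b["frequency"] = freqs[::-1]
        b["n_recombinant"] = (freqs[::-1] * 100).astype(int)
        cmp = compare_landscapes(
            Landscape(a, 100, mm.genome_length_bp / 1e6),
            Landscape(b, 100, mm.genome_length_bp / 1e6),
        )
        assert cmp.pearson_r < 0

    def test_mismatched_grids_rejected(self, small_results):
        ls = small_results.landscape()
        other = Landscape(ls.table.iloc[:-1].copy(), ls.n_gametes, ls.genome_mb)
        with pytest.raises(ValueError, match="grids"):
            compare_landscapes(ls, other)

    def test_bh_adjustment_monotone(self, small_results):
        by_treat = small_results.landscapes_by("treatment")
        cmp = compare_landscapes(*by_treat.values())
        pw = cmp.per_window.sort_values("p_raw")
        assert (np.diff(pw["p_fdr"].to_numpy()) >= -1e-12).all()
        assert (pw["p_fdr"] >= pw["p_raw"] - 1e-12).all()


class TestGroupEffects:
    def test_identical_groups_null_result(self):
        traits = pd.DataFrame(
            {
                "individual_id": [f"i{k}" for k in range(8)],
                "subpopulation": ["s"] * 8,
                "treatment": ["control"] * 4 + ["nutrient_deficiency"] * 4,
                "cc_per_chromatid": [2.0, 2.1, 1.9, 2.0] * 2,
            }
        )
        ge = group_effects(traits)
        c = ge.tukey.iloc[0]
        assert c["meandiff"] == pytest.approx(0.0)
        assert float(c["p_adj"]) > 0.9

    def test_anova_matches_manual_f_statistic(self):
        # two groups; one-way ANOVA F equals the squared two-sample t statistic
        x = np.array([2.1, 2.3, 2.2, 2.4, 2.0])
        y = np.array([1.8, 1.9, 2.0, 1.7, 1.85])
        traits = pd.DataFrame(
            {
                "individual_id": [f"i{k}" for k in range(10)],
                "subpopulation": ["s"] * 10,
                "treatment": ["a"] * 5 + ["b"] * 5,
                "cc_per_chromatid": np.concatenate([x, y]),
            }
        )
        ge = group_effects(traits)
        t, _ = sps.ttest_ind(x, y)
        f_anova = ge.anova["F"].iloc[0]
        assert f_anova == pytest.approx(t**2)

    def test_small_group_skipped_with_warning(self):
        traits = pd.DataFrame(
            {
                "individual_id": ["i1", "i2", "i3", "i4", "i5"],
                "subpopulation": ["s"] * 5,
                "treatment": ["a", "a", "b", "b", "c"],
                "cc_per_chromatid": [2.0, 2.1, 1.8, 1.9, 5.0],
            }
        )
        with pytest.warns(UserWarning, match="skipped"):
            ge = group_effects(traits)
        assert set(ge.group_means.index) == {"s:a", "s:b"}

    def test_statistics_invariant_to_record_order(self, small_results):
        t = small_results.traits
        ge1 = group_effects(t)
        ge2 = group_effects(t.sample(frac=1.0, random_state=0))
        pd.testing.assert_series_equal(ge1.group_means, ge2.group_means)


class TestAlleleStacking:
    def _traits(self, values):
        return pd.DataFrame(
            {
                "individual_id": [f"i{k}" for k in range(len(values))],
                "cc_per_chromatid": values,
            }
        )

    def test_additive_alleles_positive_rho(self, rng):
        n, m = 300, 6
        freqs = np.linspace(0.5, 0.2, m)
        ind = (rng.random((n, m)) < freqs).astype(int)
        cc = 2.0 + 0.05 * ind.sum(axis=1) + rng.normal(0, 0.05, n)
        res = allele_stacking(
            self._traits(cc), pd.DataFrame(ind, index=[f"i{k}" for k in range(n)])
        )
        assert res.spearman_rho > 0 and res.spearman_p < 0.01
        assert len(res.stacked) == m

    def test_null_alleles_small_rho(self, rng):
        n, m = 300, 6
        ind = (rng.random((n, m)) < 0.4).astype(int)
        cc = 2.0 + rng.normal(0, 0.1, n)
        res = allele_stacking(
            self._traits(cc), pd.DataFrame(ind, index=[f"i{k}" for k in range(n)])
        )
        assert abs(res.spearman_rho) < 0.15

    def test_single_allele_reduces_to_difference_of_means(self, rng):
        n = 100
        ind = (rng.random((n, 1)) < 0.5).astype(int)
        cc = 2.0 + 0.3 * ind[:, 0] + rng.normal(0, 0.01, n)
        res = allele_stacking(
            self._traits(cc), pd.DataFrame(ind, index=[f"i{k}" for k in range(n)])
        )
        carriers = ind[:, 0] == 1
        assert res.stacked["mean_trait"].iloc[0] == pytest.approx(cc[carriers].mean())

    def test_empty_subset_reported_null(self, rng):
        n = 40
        ind = np.zeros((n, 2), dtype=int)
        ind[:, 0] = 1  # nobody carries allele 2
        cc = 2.0 + rng.normal(0, 0.1, n)
        res = allele_stacking(
            self._traits(cc), pd.DataFrame(ind, index=[f"i{k}" for k in range(n)])
        )
        assert res.stacked["n_individuals"].iloc[1] == 0
        assert np.isnan(res.stacked["mean_trait"].iloc[1])
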