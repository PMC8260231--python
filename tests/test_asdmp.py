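"""Androgen-sensitive DMP screen and downstream association utilities."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import ovisclock as oc
from ovisclock.data import DataError

from conftest import make_dataset

INTACT = "sex == 'male' and not castrated"
CASTRATE = "sex == 'male' and castrated"


def _two_group_dataset(values_a, values_b, ages_a, ages_b):
    """Intact males (group a) followed by castrated males (group b)."""
    values = np.hstack([values_a, values_b])
    n_a, n_b = values_a.shape[1], values_b.shape[1]
    ds = make_dataset(values, np.concatenate([ages_a, ages_b]),
                      sex=["male"] * (n_a + n_b),
                      castrated=[False] * n_a + [True] * n_b)
    return ds


def test_identical_groups_give_t_zero_p_one():
    rng = np.random.default_rng(0)
    v = rng.uniform(0.2, 0.8, (10, 20))
    ages = rng.uniform(0, 9, 20)
    ds = _two_group_dataset(v, v, ages, ages)
    res = oc.asdmp_screen(ds, INTACT, CASTRATE)
    np.testing.assert_allclose(res["t"], 0.0, atol=1e-10)
    np.testing.assert_allclose(res["p"], 1.0, atol=1e-10)


def test_group_swap_negates_t_keeps_p():
    rng = np.random.default_rng(1)
    ds = _two_group_dataset(rng.uniform(0.2, 0.8, (15, 20)),
                            rng.uniform(0.2, 0.8, (15, 25)),
                            rng.uniform(0, 9, 20), rng.uniform(0, 9, 25))
    ab = oc.asdmp_screen(ds, INTACT, CASTRATE)
    ba = oc.asdmp_screen(ds, CASTRATE, INTACT)
    np.testing.assert_allclose(ab["t"], -ba["t"], rtol=1e-10)
    np.testing.assert_allclose(ab["p"], ba["p"], rtol=1e-10)
    np.testing.assert_allclose(ab["direction"], -ba["direction"])


def test_overlapping_group_filters_error():
    rng = np.random.default_rng(2)
    ds = _two_group_dataset(rng.uniform(0.2, 0.8, (5, 10)),
                            rng.uniform(0.2, 0.8, (5, 10)),
                            rng.uniform(0, 9, 10), rng.uniform(0, 9, 10))
    with pytest.raises(DataError, match="overlap"):
        oc.asdmp_screen(ds, "sex == 'male'", CASTRATE)


def test_slopes_and_se_match_linregress_oracle():
    """Per-group slope and SE agree with scipy.stats.linregress probe by
    probe, including probes with missing values, and the combined t/df/p
    follow the Welch slope-difference formula."""
    rng = np.random.default_rng(3)
    va = rng.uniform(0.1, 0.9, (25, 18))
    vb = rng.uniform(0.1, 0.9, (25, 22))
    va[rng.random(va.shape) < 0.08] = np.nan
    ages_a, ages_b = rng.uniform(0, 9, 18), rng.uniform(0, 9, 22)
    ds = _two_group_dataset(va, vb, ages_a, ages_b)
    res = oc.asdmp_screen(ds, INTACT, CASTRATE)
    for i in range(25):
        ok_a = ~np.isnan(va[i])
        fa = stats.linregress(ages_a[ok_a], va[i, ok_a])
        fb = stats.linregress(ages_b, vb[i])
        assert res["slope_a"].iloc[i] == pytest.approx(fa.slope, rel=1e-9)
        assert res["se_a"].iloc[i] == pytest.approx(fa.stderr, rel=1e-9)
        assert res["slope_b"].iloc[i] == pytest.approx(fb.slope, rel=1e-9)
        t_ref = (fa.slope - fb.slope) / np.hypot(fa.stderr, fb.stderr)
        assert res["t"].iloc[i] == pytest.approx(t_ref, rel=1e-9)
        va_, vb_ = fa.stderr ** 2, fb.stderr ** 2
        df_ref = (va_ + vb_) ** 2 / (va_ ** 2 / (ok_a.sum() - 2)
                                     + vb_ ** 2 / (22 - 2))
        assert res["df"].iloc[i] == pytest.approx(df_ref, rel=1e-9)
        assert res["p"].iloc[i] == pytest.approx(
            2 * stats.t.sf(abs(t_ref), df_ref), rel=1e-9)


def test_statistic_invariant_to_beta_offset_and_age_shift():
    rng = np.random.default_rng(4)
    va = rng.uniform(0.3, 0.6, (10, 15))
    vb = rng.uniform(0.3, 0.6, (10, 15))
    ages_a, ages_b = rng.uniform(1, 8, 15), rng.uniform(1, 8, 15)
    base = oc.asdmp_screen(_two_group_dataset(va, vb, ages_a, ages_b),
                           INTACT, CASTRATE)
    shifted = oc.asdmp_screen(
        _two_group_dataset(va + 0.2, vb + 0.2, ages_a + 1.0, ages_b + 1.0),
        INTACT, CASTRATE)
    np.testing.assert_allclose(base["t"], shifted["t"], rtol=1e-8)


def test_planted_slope_difference_detected_and_null_uniform():
    ds, _, truth = oc.simulate_dataset(oc.SimConfig(
        n_samples=240, n_probes=500, n_clock_probes=0, n_asdmp_probes=60,
        asdmp_slope=-0.15, noise_sd=0.3, seed=5))
    res = oc.asdmp_screen(ds, INTACT, CASTRATE)
    planted = truth.index[truth["role"] == "asdmp"]
    assert res.loc[planted, "p"].median() < 1e-5
    nulls = res.loc[res.index.difference(planted), "p"].dropna()
    assert stats.kstest(nulls, "uniform").pvalue > 0.01
    # all planted slopes are negative: top hits hypomethylate in intact males
    top = oc.rank_and_select(res, 50)
    assert (res.loc[top, "direction"] < 0).sum() >= 48


class TestRankAndSelect:
    def _results(self, p, t, probes=None):
        probes = probes or [f"p{i}" for i in range(len(p))]
        return pd.DataFrame({"probe_id": probes, "p": p, "t": t,
                             "ok": [True] * len(p)})

    def test_k_zero_empty(self):
        assert oc.rank_and_select(self._results([0.1], [1.0]), 0) == []

    def test_equal_p_breaks_ties_by_abs_t_then_id(self):
        res = self._results([0.5, 0.5, 0.5], [1.0, -2.0, 1.0],
                            probes=["b", "a", "c"])
        assert oc.rank_and_select(res, 3) == ["a", "b", "c"]

    def test_matches_sort_oracle(self):
        rng = np.random.default_rng(6)
        p = rng.choice([0.01, 0.5, 0.9], 50)
        t = rng.normal(0, 2, 50)
        res = self._results(p, t)
        expected = sorted(range(50), key=lambda i: (p[i], -abs(t[i]), f"p{i}"))
        assert oc.rank_and_select(res, 50) == [f"p{i}" for i in expected]


class TestChromDistribution:
    def _annotation(self, chroms):
        ann = pd.DataFrame({
            "probe_id": [f"p{i}" for i in range(len(chroms))],
            "chrom": chroms, "start": 0, "end": 2, "mapped": True})
        return ann.set_index("probe_id", drop=False)

    def test_universe_as_list_matches_expectation_exactly(self):
        ann = self._annotation(["chr1"] * 10 + ["chr2"] * 30)
        universe = [f"p{i}" for i in range(40)]
        out = oc.chrom_distribution(universe, ann, universe)
        assert out["p"] == pytest.approx(1.0)
        pd.testing.assert_series_equal(
            out["table"]["observed"].astype(float), out["table"]["expected"],
            check_names=False)

    def test_concentration_on_one_chromosome_detected(self):
        ann = self._annotation([f"chr{1 + i % 10}" for i in range(500)])
        universe = [f"p{i}" for i in range(500)]
        hits = [p for p in universe
                if ann.loc[p, "chrom"] == "chr3"][:40]
        out = oc.chrom_distribution(hits, ann, universe)
        assert out["p"] < 1e-10

    def test_uniform_draws_rarely_significant(self):
        ann = self._annotation([f"chr{1 + i % 10}" for i in range(500)])
        universe = np.array([f"p{i}" for i in range(500)])
        rng = np.random.default_rng(7)
        hits = [oc.chrom_distribution(rng.choice(universe, 60, replace=False),
                                      ann, list(universe))["p"] > 0.05
                for _ in range(100)]
        assert np.mean(hits) >= 0.9


class TestMassWindow:
    def _juvenile_males(self, betas, mass, castrated):
        n = betas.shape[1]
        return make_dataset(betas, np.full(n, 0.6), sex=["male"] * n,
                            castrated=castrated, mass=mass)

    def test_identical_groups_z_zero_p_one(self):
        rng = np.random.default_rng(8)
        half = rng.uniform(0.2, 0.8, (8, 20))
        betas = np.hstack([half, half])
        mass = np.concatenate([np.linspace(25, 40, 20)] * 2)
        ds = self._juvenile_males(betas, mass, [False] * 20 + [True] * 20)
        out = oc.mass_window_association(ds, [f"p{i}" for i in range(8)],
                                         window_width=4)
        np.testing.assert_allclose(out["z"], 0.0, atol=1e-12)
        np.testing.assert_allclose(out["p"], 1.0, atol=1e-12)

    def test_constant_window_flagged(self):
        rng = np.random.default_rng(9)
        betas = np.vstack([np.full((4, 20), 0.5),
                           rng.uniform(0.2, 0.8, (4, 20))])
        mass = np.linspace(25, 40, 20)
        ds = self._juvenile_males(betas, mass, [False] * 10 + [True] * 10)
        out = oc.mass_window_association(ds, [f"p{i}" for i in range(8)],
                                         window_width=4)
        assert not out.loc[1, "ok"] and out.loc[2, "ok"]

    def test_missing_mass_listed(self):
        betas = np.random.default_rng(10).uniform(0.2, 0.8, (8, 10))
        mass = np.array([np.nan] + [30.0] * 9)
        ds = self._juvenile_males(betas, mass, [False] * 5 + [True] * 5)
        with pytest.raises(DataError, match="s0"):
            oc.mass_window_association(ds, [f"p{i}" for i in range(8)],
                                       window_width=4)

    def test_too_few_windows(self):
        betas = np.random.default_rng(11).uniform(0.2, 0.8, (8, 10))
        ds = self._juvenile_males(betas, np.full(10, 30.0),
                                  [False] * 5 + [True] * 5)
        with pytest.raises(DataError, match="windows"):
            oc.mass_window_association(ds, [f"p{i}" for i in range(8)],
                                       window_width=8)

    def test_planted_opposite_coupling_detected(self):
        """Opposite-sign mass-methylation coupling (|r|=0.5, n=40/group) is
        detected in the first window >=80% of the time."""
        rng = np.random.default_rng(12)
        hits = 0
        n_rep, w = 200, 10
        for _ in range(n_rep):
            z = rng.standard_normal((2, 40))  # latent window methylation
            noise = rng.standard_normal((2, 40))
            mass_i = 35 - 0.5 * 3 * z[0] + 3 * np.sqrt(0.75) * noise[0]
            mass_c = 30 + 0.5 * 3 * z[1] + 3 * np.sqrt(0.75) * noise[1]
            beta_i = 0.5 + 0.05 * z[0][None, :] \
                + 0.01 * rng.standard_normal((2 * w, 40))
            beta_c = 0.5 + 0.05 * z[1][None, :] \
                + 0.01 * rng.standard_normal((2 * w, 40))
            ds = self._juvenile_males(
                np.clip(np.hstack([beta_i, beta_c]), 0.01, 0.99),
                np.concatenate([mass_i, mass_c]),
                [False] * 40 + [True] * 40)
            out = oc.mass_window_association(
                ds, [f"p{i}" for i in range(2 * w)], window_width=w)
            hits += out.loc[1, "p"] < 0.05
        assert hits / n_rep >= 0.8


class TestDimorphismExpression:
    def test_equal_values_p_one(self):
        out = oc.dimorphism_expression_test(
            {"kidney": 2.0, "muscle": 2.0, "liver": 2.0, "cortex": 2.0},
            {"kidney": True, "muscle": True, "liver": False, "cortex": False})
        assert out["t"] == 0.0 and out["p"] == pytest.approx(1.0)

    def test_matches_pooled_t_closed_form(self):
        out = oc.dimorphism_expression_test(
            {"a": 7.0, "b": 8.0, "c": 9.0, "x": 1.0, "y": 2.0, "z": 3.0},
            {"a": True, "b": True, "c": True,
             "x": False, "y": False, "z": False})
        # pooled-variance t for {7,8,9} vs {1,2,3}: t = 6 / sqrt(2/3)
        t_ref = 6.0 / np.sqrt(2.0 / 3.0)
        assert out["t"] == pytest.approx(t_ref, rel=1e-12)
        assert out["p"] == pytest.approx(2 * stats.t.sf(t_ref, 4), rel=1e-12)

    def test_single_tissue_class_error(self):
        with pytest.raises(DataError, match=">= 2 tissues"):
            oc.dimorphism_expression_test(
                {"a": 1.0, "b": 2.0, "c": 3.0},
                {"a": True, "b": False, "c": False})


def test_fisher_z_known_value():
    # r1=0.5 (n=50) vs r2=-0.5 (n=50): z = 2*atanh(0.5)/sqrt(2/47)
    z, p = oc.fisher_z_diff(0.5, 50, -0.5, 50)
    z_ref = 2 * np.arctanh(0.5) / np.sqrt(2 / 47)
    assert z == pytest.approx(z_ref, rel=1e-12)
    assert p == pytest.approx(2 * stats.norm.sf(z_ref), rel=1e-12)
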