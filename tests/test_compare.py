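"""t-tests, Dunnett comparisons, adjusted means, and trait correlations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import metgain as mg

from conftest import make_balanced_dataset


class TestTTest:
    def test_identical_groups(self):
        g = [1.0, 2.0, 3.0, 4.0]
        res = mg.mean_shift_ttest(g, g)
        assert res.statistic == 0.0
        assert res.pvalue == pytest.approx(1.0)

    def test_group_size_guard(self):
        with pytest.raises(ValueError):
            mg.mean_shift_ttest([1.0], [1.0, 2.0])

    def test_power_at_two_sd_shift(self):
        # noncentral-t oracle: delta = 2 pooled SD at n = 10 per group gives
        # power ~0.98 at alpha = 0.05, so the empirical rejection rate over
        # 300 simulations must exceed 0.95
        rng = np.random.default_rng(77)
        rejections = 0
        n_sim = 300
        for _ in range(n_sim):
            a = rng.normal(0.0, 1.0, 10)
            b = rng.normal(2.0, 1.0, 10)
            if mg.mean_shift_ttest(a, b).pvalue < 0.05:
                rejections += 1
        assert rejections / n_sim > 0.95

    def test_pooled_variant_available(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 8), rng.normal(0, 2, 8)
        welch = mg.mean_shift_ttest(a, b)
        pooled = mg.mean_shift_ttest(a, b, equal_var=True)
        assert welch.df != pooled.df


class TestDunnett:
    def test_single_comparison_equals_unadjusted(self):
        rng = np.random.default_rng(5)
        g = [rng.normal(0, 1, 12)]
        c = rng.normal(0, 1, 12)
        out = mg.dunnett_many_to_one(g, c, seed=1)
        assert out["p_adjusted"].iloc[0] == pytest.approx(
            out["p_unadjusted"].iloc[0], abs=5e-3
        )

    def test_dominates_bonferroni(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            k = int(rng.integers(2, 5))
            groups = [rng.normal(rng.normal(0, 1), 1, 8) for _ in range(k)]
            ctrl = rng.normal(0, 1, 8)
            out = mg.dunnett_many_to_one(groups, ctrl, seed=2)
            bonf = np.minimum(1.0, k * out["p_unadjusted"])
            assert (out["p_adjusted"] <= bonf + 5e-3).all()
            # and adjusted never below unadjusted
            assert (out["p_adjusted"] >= out["p_unadjusted"] - 5e-3).all()

    def test_adjusted_p_monotone_in_statistic(self):
        rng = np.random.default_rng(13)
        groups = [rng.normal(m, 1, 10) for m in (0.0, 0.5, 1.5, 3.0)]
        ctrl = rng.normal(0, 1, 10)
        out = mg.dunnett_many_to_one(groups, ctrl, seed=3)
        order = out.sort_values("statistic", key=np.abs, ascending=False)
        assert order["p_adjusted"].is_monotonic_increasing

    def test_degenerate_control_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            mg.dunnett_many_to_one([[1.0, 1.0]], [2.0, 2.0])

    def test_reproducible_under_seed(self):
        rng = np.random.default_rng(4)
        groups = [rng.normal(0, 1, 10) for _ in range(3)]
        ctrl = rng.normal(0, 1, 10)
        a = mg.dunnett_many_to_one(groups, ctrl, seed=42)
        b = mg.dunnett_many_to_one(groups, ctrl, seed=42)
        pd.testing.assert_frame_equal(a, b)


class TestAdjustedMeans:
    def test_balanced_equals_arithmetic(self):
        ds = make_balanced_dataset(g=5, seed=6)
        adj = mg.adjusted_means(ds, "yield")
        raw = mg.entry_means(ds, "yield").set_index("entry")["mean"]
        for e in raw.index:
            assert adj[e] == pytest.approx(raw[e], rel=1e-10)

    def test_constant_data(self):
        ds = make_balanced_dataset(g=3, seed=1)
        ds.data["yield"] = 42.0
        adj = mg.adjusted_means(ds, "yield")
        assert np.allclose(adj, 42.0)

    def test_missing_cell_matches_normal_equations(self):
        # 3 entries x 2 treatments, one cell removed: compare with a direct
        # least-squares solve of the additive two-factor model
        rows = []
        vals = iter([10.0, 12.0, 14.0, 20.0, 13.0, 25.0])
        for e in ("a", "b", "c"):
            for t in ("RI", "RF"):
                rows.append(dict(entry=e, treatment=t, year=1, rep=1, yield_=next(vals)))
        df = pd.DataFrame(rows).rename(columns={"yield_": "yield"})
        df = df.drop(index=5).reset_index(drop=True)  # drop (c, RF)
        ds = mg.TrialDataset(df, ["yield"])
        adj = mg.adjusted_means(ds, "yield")

        # oracle: y ~ intercept + entry dummies + treatment dummy via lstsq,
        # adjusted mean = prediction averaged over both treatments
        ent = {"b": 1, "c": 2}
        X = []
        for _, r in df.iterrows():
            row = [1.0, 0.0, 0.0, 0.0]
            if r["entry"] in ent:
                row[ent[r["entry"]]] = 1.0
            row[3] = 1.0 if r["treatment"] == "RF" else 0.0
            X.append(row)
        beta, *_ = np.linalg.lstsq(np.array(X), df["yield"].to_numpy(), rcond=None)
        for i, e in enumerate(("a", "b", "c")):
            pred = beta[0] + (beta[ent[e]] if e in ent else 0.0) + 0.5 * beta[3]
            assert adj[e] == pytest.approx(pred, rel=1e-9)

    def test_absent_trait(self):
        ds = make_balanced_dataset(g=3, seed=1)
        with pytest.raises(KeyError):
            mg.adjusted_means(ds, "ndvi")


class TestTraitCorrelations:
    def test_self_correlation_unit_and_flagged(self):
        rng = np.random.default_rng(2)
        m = pd.DataFrame({"a": rng.normal(0, 1, 10), "b": rng.normal(0, 1, 10)})
        res = mg.trait_correlations(m)
        assert res.r.loc["a", "a"] == 1.0
        assert bool(res.significant.loc["a", "a"])
        assert np.allclose(res.r, res.r.T, equal_nan=True)

    def test_fisher_z_coverage_at_rho_half(self):
        # estimate must land inside the 95% Fisher-z interval around 0.5 in
        # at least 93% of simulations (n = 150 entries per simulation)
        rng = np.random.default_rng(10)
        n, rho, hits, n_sim = 150, 0.5, 0, 200
        half_width = 1.959964 / np.sqrt(n - 3)
        lo, hi = np.tanh(np.arctanh(rho) - half_width), np.tanh(
            np.arctanh(rho) + half_width
        )
        for _ in range(n_sim):
            x = rng.normal(0, 1, n)
            y = rho * x + np.sqrt(1 - rho**2) * rng.normal(0, 1, n)
            r = mg.trait_correlations(pd.DataFrame({"x": x, "y": y})).r.loc["x", "y"]
            hits += lo <= r <= hi
        assert hits / n_sim >= 0.93

    def test_negative_dependence_recovered_and_flagged(self):
        # biomass up, harvest index down: the generated negative dependence
        # must come back with a negative sign and a significance flag
        rng = np.random.default_rng(55)
        biomass = rng.normal(1600, 120, 60)
        hi = 0.9 - 0.0003 * biomass + rng.normal(0, 0.01, 60)
        res = mg.trait_correlations(pd.DataFrame({"biomass": biomass, "hi": hi}))
        assert res.r.loc["biomass", "hi"] < 0
        assert bool(res.significant.loc["biomass", "hi"])

    def test_too_few_entries(self):
        with pytest.raises(ValueError):
            mg.trait_correlations(pd.DataFrame({"a": [1.0, 2.0], "b": [2.0, 1.0]}))

    def test_constant_trait_missing_with_warning(self, caplog):
        m = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0], "b": [5.0] * 4})
        with caplog.at_level("WARNING"):
            res = mg.trait_correlations(m)
        assert np.isnan(res.r.loc["a", "b"])
        assert any("constant" in r.message for r in caplog.records)
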