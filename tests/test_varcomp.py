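"""Balanced ANOVA, variance components, heritability, and gain arithmetic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import metgain as mg
from metgain.trial import UnbalancedDataError

from conftest import make_balanced_dataset
from helpers_oracle import exact_anova, exact_varcomps


class TestAnova:
    def test_constant_data_all_ss_zero(self):
        ds = make_balanced_dataset(g=3, seed=0)
        ds.data["yield"] = 5.0
        an = mg.anova_three_way(ds, "yield")
        assert (an["ss"].abs() < 1e-20).all()

    @pytest.mark.parametrize("g,seed", [(2, 4), (3, 11), (3, 23)])
    def test_matches_exact_rational_oracle(self, g, seed):
        ds = make_balanced_dataset(g=g, t=2, y=2, r=2, seed=seed, integer=True)
        an = mg.anova_three_way(ds, "yield")
        df = ds.data.rename(columns={"yield": "y"})
        oracle = exact_anova(df, "y")
        for source, ss in oracle.items():
            assert an.loc[source, "ss"] == pytest.approx(float(ss), rel=1e-10, abs=1e-10)
        assert an.drop("total")["ss"].sum() == pytest.approx(
            an.loc["total", "ss"], rel=1e-12
        )

    def test_pure_noise_mean_squares_all_near_error(self):
        # with only residual variance every factor mean square estimates
        # sigma2_e, i.e. all F ratios hover around 1
        spec = mg.VarCompSpec(
            sigma2_G=0, sigma2_GT=0, sigma2_GY=0, sigma2_GTY=0, sigma2_e=9.0
        )
        dims = mg.DesignDims(g=30, t=2, y=2, r=2)
        sums = {}
        for s in range(40):
            an = mg.anova_three_way(
                mg.simulate_met(spec, dims, seed=500 + s), "yield"
            )
            for src in ("genotype", "genotype:treatment", "genotype:year",
                        "genotype:treatment:year", "residual"):
                sums.setdefault(src, []).append(an.loc[src, "ms"])
        for src, vals in sums.items():
            assert np.mean(vals) == pytest.approx(9.0, rel=0.15)

    def test_unbalanced_raises_with_cell(self):
        ds = make_balanced_dataset(g=3, seed=2)
        broken = mg.TrialDataset(ds.data.iloc[1:], ds.trait_names)
        with pytest.raises(UnbalancedDataError):
            mg.anova_three_way(broken, "yield")

    def test_missing_value_raises(self):
        ds = make_balanced_dataset(g=3, seed=2)
        ds.data.loc[0, "yield"] = np.nan
        with pytest.raises(UnbalancedDataError, match="missing"):
            mg.anova_three_way(ds, "yield")


class TestVarcomps:
    def test_all_ms_equal_gives_zero_components(self):
        dims = mg.DesignDims(g=5, t=2, y=2, r=2)
        ms = pd.DataFrame(
            {"ms": 4.0, "df": [dims.g - 1, 4, 4, 4, 36], "ss": 1.0},
            index=pd.Index(
                ["genotype", "genotype:treatment", "genotype:year",
                 "genotype:treatment:year", "residual"],
                name="source",
            ),
        )
        vc = mg.estimate_varcomps(ms, dims)
        assert vc.sigma2_G == vc.sigma2_GT == vc.sigma2_GY == vc.sigma2_GTY == 0.0
        assert vc.sigma2_e == 4.0

    def test_matches_oracle_on_integer_fixture(self, small_integer_ds):
        an = mg.anova_three_way(small_integer_ds, "yield")
        vc = mg.estimate_varcomps(an, small_integer_ds.design)
        oracle = exact_varcomps(
            exact_anova(small_integer_ds.data.rename(columns={"yield": "y"}), "y"),
            3, 2, 2, 2,
        )
        for name, val in oracle.items():
            assert getattr(vc, name) == pytest.approx(float(val), rel=1e-10, abs=1e-10)

    def test_negative_component_flagged(self, small_integer_ds):
        an = mg.anova_three_way(small_integer_ds, "yield")
        vc = mg.estimate_varcomps(an, small_integer_ds.design)
        # this fixture happens to produce a negative 3-way component
        assert "sigma2_GTY" in vc.negative
        assert vc.sigma2_GTY < 0

    def test_dims_mismatch_rejected(self, small_integer_ds):
        an = mg.anova_three_way(small_integer_ds, "yield")
        with pytest.raises(ValueError, match="inconsistent"):
            mg.estimate_varcomps(an, mg.DesignDims(g=10, t=2, y=2, r=2))


class TestHeritability:
    def test_zero_genetic_variance(self):
        vc = mg.VarComps(0.0, 2, 2, 2, 8, mg.DesignDims(10, 2, 2, 2))
        assert mg.broad_sense_heritability(vc) == 0.0

    def test_perfect_repeatability(self):
        vc = mg.VarComps(5.0, 0, 0, 0, 0, mg.DesignDims(10, 2, 2, 2))
        assert mg.broad_sense_heritability(vc) == 100.0

    def test_hand_worked_example(self):
        # denominator 4 + 2/2 + 2/2 + 2/4 + 8/8 = 7.5 -> H = 53.33%
        vc = mg.VarComps(4.0, 2.0, 2.0, 2.0, 8.0, mg.DesignDims(10, 2, 2, 2))
        assert mg.broad_sense_heritability(vc) == pytest.approx(400 / 7.5)

    def test_all_zero_components_return_zero(self):
        vc = mg.VarComps(0, 0, 0, 0, 0, mg.DesignDims(10, 2, 2, 2))
        assert mg.broad_sense_heritability(vc) == 0.0

    def test_negative_components_truncated(self):
        vc = mg.VarComps(4.0, -3.0, 0, 0, 0, mg.DesignDims(10, 2, 2, 2))
        assert mg.broad_sense_heritability(vc) == 100.0

    @given(
        s2g=st.floats(0.1, 100),
        other=st.floats(0.0, 100),
        bump=st.floats(0.1, 50),
    )
    def test_monotone_in_components(self, s2g, other, bump):
        dims = mg.DesignDims(10, 2, 2, 2)
        base = mg.broad_sense_heritability(
            mg.VarComps(s2g, other, other, other, other, dims)
        )
        up_g = mg.broad_sense_heritability(
            mg.VarComps(s2g + bump, other, other, other, other, dims)
        )
        up_e = mg.broad_sense_heritability(
            mg.VarComps(s2g, other, other, other, other + bump, dims)
        )
        assert up_g >= base >= up_e

    @pytest.mark.parametrize("scale", [0.1, 3.0, 100.0])
    def test_scale_invariance_of_h_and_linearity_of_ga(self, scale):
        ds = make_balanced_dataset(g=8, seed=3)
        scaled = mg.TrialDataset(
            ds.data.assign(**{"yield": ds.data["yield"] * scale}), ["yield"]
        )
        a = mg.gain_summary(ds, "yield")
        b = mg.gain_summary(scaled, "yield")
        assert b.H_BS == pytest.approx(a.H_BS, rel=1e-9)
        assert b.GA == pytest.approx(a.GA * scale, rel=1e-9)


class TestGainArithmetic:
    def test_ga_zero_when_h_zero(self):
        assert mg.genetic_advance(10.0, 0.0) == 0.0

    def test_ga_zero_when_k_zero(self):
        assert mg.genetic_advance(10.0, 50.0, K=0.0) == 0.0

    def test_ga_inversion_loop_closes(self):
        # base-population yield workup: GA 74.84 at H = 29.81% implies
        # sigmaP = GA / (K * H); feeding that back must return GA exactly
        sigmaP = 74.84 / (2.06 * 0.2981)
        assert mg.genetic_advance(sigmaP, 29.81) == pytest.approx(74.84, rel=1e-12)

    def test_negative_sigma_p_rejected(self):
        with pytest.raises(ValueError):
            mg.genetic_advance(-1.0, 50.0)

    @pytest.mark.parametrize(
        "ga,mean,expected",
        [(74.84, 513.4, 14.58), (57.4, 601.2, 9.55), (0.0, 100.0, 0.0)],
    )
    def test_genetic_gain_percent(self, ga, mean, expected):
        assert mg.genetic_gain_percent(ga, mean) == pytest.approx(expected, abs=0.005)

    def test_gain_percent_rejects_nonpositive_mean(self):
        with pytest.raises(ValueError):
            mg.genetic_gain_percent(10.0, 0.0)

    @pytest.mark.parametrize(
        "mean,ref,expected",
        [(100.0, 100.0, 0.0), (601.2, 513.4, 17.1), (110.0, 100.0, 10.0)],
    )
    def test_gain_over_reference(self, mean, ref, expected):
        assert mg.gain_over_reference(mean, ref) == pytest.approx(expected, abs=0.05)

    def test_gain_over_reference_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            mg.gain_over_reference(10.0, 0.0)


class TestGainSummary:
    def test_summary_composes_pieces(self):
        ds = make_balanced_dataset(g=12, seed=21)
        s = mg.gain_summary(ds, "yield", label="all", f5_mean=480.0)
        assert s.gain_pct == pytest.approx(s.GA / s.mean * 100)
        assert s.gain_over_F5_pct == pytest.approx(
            (s.mean - 480.0) / 480.0 * 100
        )
        assert 0 <= s.H_BS <= 100

    def test_per_family_runs_each_family_separately(self):
        ds = make_balanced_dataset(g=6, seed=8)
        d = ds.data.copy()
        d["family"] = np.where(d["entry"].isin(["e0", "e1", "e2"]), "f1", "f2")
        fam_ds = mg.TrialDataset(d, ["yield"])
        out = mg.per_family_gain_summaries(fam_ds, "yield")
        assert [s.label for s in out] == ["f1", "f2"]
        sub = fam_ds.subset(family="f1")
        assert out[0].mean == pytest.approx(sub.data["yield"].mean())
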