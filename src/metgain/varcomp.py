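"""Variance components, broad-sense heritability, and genetic gain.

For a balanced genotype x treatment x year trial with replicates nested in
treatment-year, the analysis of variance decomposes the total sum of squares
exactly into G, T, Y, GT, GY, TY, GTY, replicate-within-(T,Y), and residual
terms.  Method-of-moments (expected-mean-squares) estimators then recover
the random-model variance components, from which broad-sense heritability
on an entry-mean basis is

    H_BS = sigma2_G / (sigma2_G + sigma2_GT/t + sigma2_GY/y
                       + sigma2_GTY/(t*y) + sigma2_e/(r*t*y)) * 100

and the expected response to truncation selection (genetic advance) is
GA = K * sigmaP * H_BS/100 with K the standardized selection intensity
(2.06 for the top 5% of a normal distribution).

The closed-form path deliberately requires balance: on unbalanced data the
expected-mean-squares algebra no longer holds and a distinct
:class:`~metgain.trial.UnbalancedDataError` is raised instead of silently
dropping plots.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trial import DesignDims, TrialDataset, UnbalancedDataError, entry_means

logger = logging.getLogger(__name__)

ANOVA_SOURCES = (
    "genotype",
    "treatment",
    "year",
    "genotype:treatment",
    "genotype:year",
    "treatment:year",
    "genotype:treatment:year",
    "rep(treatment:year)",
    "residual",
    "total",
)


def _check_balance(d: pd.DataFrame, trait: str, dims: DesignDims) -> None:
    if d[trait].isna().any():
        n = int(d[trait].isna().sum())
        raise UnbalancedDataError(
            f"{n} missing value(s) for trait '{trait}'; the closed-form "
            "ANOVA requires complete data"
        )
    counts = d.groupby(["entry", "treatment", "year"], sort=False)[trait].count()
    expected_cells = dims.g * dims.t * dims.y
    bad = counts[counts != dims.r]
    if len(counts) != expected_cells or not bad.empty:
        missing = bad.head(10).index.tolist()
        raise UnbalancedDataError(
            f"layout is not a complete {dims.g}x{dims.t}x{dims.y} design with "
            f"r={dims.r} plots per cell; offending cells (entry, treatment, "
            f"year): {missing}"
        )


def anova_three_way(ds: TrialDataset, trait: str) -> pd.DataFrame:
    """Exact balanced ANOVA table (ss, df, ms) for one trait.

    The sum-of-squares partition is exact: the component rows add up to the
    total row.  Raises :class:`UnbalancedDataError` on incomplete layouts.
    """
    if trait not in ds.trait_names:
        raise KeyError(f"trait '{trait}' not in dataset")
    dims = ds.design
    if dims.g < 2:
        raise ValueError("ANOVA needs >= 2 entries")
    d = ds.data[["entry", "treatment", "year", "rep", trait]]
    _check_balance(d, trait, dims)
    g, t, y, r = dims.g, dims.t, dims.y, dims.r

    yv = d[trait].to_numpy(float)
    grand = yv.mean()

    def mean_by(cols):
        return d.groupby(cols, sort=True)[trait].mean()

    m_g = mean_by(["entry"])
    m_t = mean_by(["treatment"])
    m_y = mean_by(["year"])
    m_gt = mean_by(["entry", "treatment"])
    m_gy = mean_by(["entry", "year"])
    m_ty = mean_by(["treatment", "year"])
    m_gty = mean_by(["entry", "treatment", "year"])
    m_tyr = mean_by(["treatment", "year", "rep"])

    ss_g = t * y * r * ((m_g - grand) ** 2).sum()
    ss_t = g * y * r * ((m_t - grand) ** 2).sum()
    ss_y = g * t * r * ((m_y - grand) ** 2).sum()

    dev_gt = (
        m_gt
        - m_g.reindex(m_gt.index.get_level_values("entry")).to_numpy()
        - m_t.reindex(m_gt.index.get_level_values("treatment")).to_numpy()
        + grand
    )
    ss_gt = y * r * (dev_gt ** 2).sum()
    dev_gy = (
        m_gy
        - m_g.reindex(m_gy.index.get_level_values("entry")).to_numpy()
        - m_y.reindex(m_gy.index.get_level_values("year")).to_numpy()
        + grand
    )
    ss_gy = t * r * (dev_gy ** 2).sum()
    dev_ty = (
        m_ty
        - m_t.reindex(m_ty.index.get_level_values("treatment")).to_numpy()
        - m_y.reindex(m_ty.index.get_level_values("year")).to_numpy()
        + grand
    )
    ss_ty = g * r * (dev_ty ** 2).sum()

    dev_gty = (
        m_gty
        - m_gt.reindex(
            m_gty.index.droplevel("year")
        ).to_numpy()
        - m_gy.reindex(
            m_gty.index.droplevel("treatment")
        ).to_numpy()
        - m_ty.reindex(
            m_gty.index.droplevel("entry")
        ).to_numpy()
        + m_g.reindex(m_gty.index.get_level_values("entry")).to_numpy()
        + m_t.reindex(m_gty.index.get_level_values("treatment")).to_numpy()
        + m_y.reindex(m_gty.index.get_level_values("year")).to_numpy()
        - grand
    )
    ss_gty = r * (dev_gty ** 2).sum()

    dev_rep = m_tyr - m_ty.reindex(m_tyr.index.droplevel("rep")).to_numpy()
    ss_rep = g * (dev_rep ** 2).sum()

    ss_total = ((yv - grand) ** 2).sum()
    ss_resid = ss_total - (
        ss_g + ss_t + ss_y + ss_gt + ss_gy + ss_ty + ss_gty + ss_rep
    )
    # the partition is exact; tiny negatives are floating-point noise
    if ss_resid < 0:
        if ss_resid < -1e-8 * max(ss_total, 1.0):
            raise AssertionError("sum-of-squares partition failed")
        ss_resid = 0.0

    df_map = {
        "genotype": g - 1,
        "treatment": t - 1,
        "year": y - 1,
        "genotype:treatment": (g - 1) * (t - 1),
        "genotype:year": (g - 1) * (y - 1),
        "treatment:year": (t - 1) * (y - 1),
        "genotype:treatment:year": (g - 1) * (t - 1) * (y - 1),
        "rep(treatment:year)": t * y * (r - 1),
        "residual": (g - 1) * t * y * (r - 1),
        "total": g * t * y * r - 1,
    }
    ss_map = {
        "genotype": ss_g,
        "treatment": ss_t,
        "year": ss_y,
        "genotype:treatment": ss_gt,
        "genotype:year": ss_gy,
        "treatment:year": ss_ty,
        "genotype:treatment:year": ss_gty,
        "rep(treatment:year)": ss_rep,
        "residual": ss_resid,
        "total": ss_total,
    }
    out = pd.DataFrame(
        {
            "ss": [ss_map[s] for s in ANOVA_SOURCES],
            "df": [df_map[s] for s in ANOVA_SOURCES],
        },
        index=pd.Index(ANOVA_SOURCES, name="source"),
    )
    out["ms"] = np.where(out["df"] > 0, out["ss"] / out["df"].replace(0, 1), np.nan)
    out.loc["total", "ms"] = np.nan
    return out


@dataclass
class VarComps:
    """Method-of-moments variance-component estimates.

    Negative estimates (possible whenever a mean square falls below the one
    it is contrasted with) are retained as estimated and listed in
    ``negative``; heritability truncates them to zero.
    """

    sigma2_G: float
    sigma2_GT: float
    sigma2_GY: float
    sigma2_GTY: float
    sigma2_e: float
    dims: DesignDims
    negative: tuple[str, ...] = field(default_factory=tuple)


def estimate_varcomps(ms: pd.DataFrame, dims: DesignDims) -> VarComps:
    """Solve the expected-mean-squares equations of the random 3-way model.

    sigma2_e   = MS_resid
    sigma2_GTY = (MS_GTY - MS_resid) / r
    sigma2_GY  = (MS_GY - MS_GTY) / (r t)
    sigma2_GT  = (MS_GT - MS_GTY) / (r y)
    sigma2_G   = (MS_G - MS_GT - MS_GY + MS_GTY) / (r t y)
    """
    needed = {
        "genotype",
        "genotype:treatment",
        "genotype:year",
        "genotype:treatment:year",
        "residual",
    }
    if not needed.issubset(ms.index):
        raise ValueError(f"mean-squares table lacks rows: {needed - set(ms.index)}")
    g, t, y, r = dims.g, dims.t, dims.y, dims.r
    if ms.loc["genotype", "df"] != g - 1:
        raise ValueError(
            f"dims (g={g}) inconsistent with ANOVA table df "
            f"({ms.loc['genotype', 'df']} for genotype)"
        )
    ms_g = ms.loc["genotype", "ms"]
    ms_gt = ms.loc["genotype:treatment", "ms"]
    ms_gy = ms.loc["genotype:year", "ms"]
    ms_gty = ms.loc["genotype:treatment:year", "ms"]
    ms_e = ms.loc["residual", "ms"]
    # with a single-level factor the corresponding interaction terms vanish;
    # substituting so the general contrasts collapse to the 1- and 2-way EMS
    if t == 1 or y == 1:
        ms_gty = ms_e
    if t == 1:
        ms_gt = ms_gty
    if y == 1:
        ms_gy = ms_gty

    est = {
        "sigma2_e": ms_e,
        "sigma2_GTY": (ms_gty - ms_e) / r if (t > 1 and y > 1) else 0.0,
        "sigma2_GY": (ms_gy - ms_gty) / (r * t) if y > 1 else 0.0,
        "sigma2_GT": (ms_gt - ms_gty) / (r * y) if t > 1 else 0.0,
        "sigma2_G": (ms_g - ms_gt - ms_gy + ms_gty) / (r * t * y),
    }
    negative = tuple(k for k, v in est.items() if v < 0)
    if negative:
        logger.warning("negative variance-component estimate(s): %s", negative)
    return VarComps(
        sigma2_G=est["sigma2_G"],
        sigma2_GT=est["sigma2_GT"],
        sigma2_GY=est["sigma2_GY"],
        sigma2_GTY=est["sigma2_GTY"],
        sigma2_e=est["sigma2_e"],
        dims=dims,
        negative=negative,
    )


def broad_sense_heritability(vc: VarComps) -> float:
    """Broad-sense heritability (percent) on an entry-mean basis.

    Negative component estimates are truncated to zero here so the result
    stays in [0, 100].  Returns 0 (with a log note) when every component is
    zero.
    """
    t, y, r = vc.dims.t, vc.dims.y, vc.dims.r
    s2g = max(vc.sigma2_G, 0.0)
    denom = (
        s2g
        + max(vc.sigma2_GT, 0.0) / t
        + max(vc.sigma2_GY, 0.0) / y
        + max(vc.sigma2_GTY, 0.0) / (t * y)
        + max(vc.sigma2_e, 0.0) / (r * y * t)
    )
    if denom == 0.0:
        logger.warning("all variance components zero; heritability undefined, returning 0")
        return 0.0
    return s2g / denom * 100.0


def genetic_advance(sigmaP: float, H_pct: float, K: float = 2.06) -> float:
    """Expected selection response GA = K * sigmaP * H (H as a fraction)."""
    if sigmaP < 0:
        raise ValueError("sigmaP must be >= 0")
    if not (0 <= H_pct <= 100):
        raise ValueError("heritability percent must lie in [0, 100]")
    return K * sigmaP * (H_pct / 100.0)


def genetic_gain_percent(GA: float, mean: float) -> float:
    """Genetic gain as a percentage of the population mean."""
    if mean <= 0:
        raise ValueError("mean must be > 0 to express gain as a percentage")
    return GA / mean * 100.0


def gain_over_reference(mean: float, ref_mean: float) -> float:
    """Percent difference of a population mean from a reference entry's mean.

    Negative values mean the population sits below the reference.
    """
    if ref_mean <= 0:
        raise ValueError("reference mean must be > 0")
    return (mean - ref_mean) / ref_mean * 100.0


@dataclass
class GainSummary:
    """Per-population gain statistics for one trait."""

    trait: str
    label: str
    mean: float
    sigmaP: float
    H_BS: float
    K: float
    GA: float
    gain_pct: float
    gain_over_F5_pct: float | None = None
    gain_over_check_pct: float | None = None

    def as_row(self) -> dict:
        return {
            "line": self.label,
            "trait": self.trait,
            "mean": self.mean,
            "sigmaP": self.sigmaP,
            "H_BS": self.H_BS,
            "GA": self.GA,
            "genetic_gain_pct": self.gain_pct,
            "gain_over_F5_pct": self.gain_over_F5_pct,
            "gain_over_check_pct": self.gain_over_check_pct,
        }


def gain_summary(
    ds: TrialDataset,
    trait: str,
    label: str = "",
    K: float = 2.06,
    f5_mean: float | None = None,
    check_mean: float | None = None,
    sigma_p_basis: str = "entry_mean",
) -> GainSummary:
    """Full gain workup of one population: ANOVA -> H_BS -> GA -> gain %.

    ``sigma_p_basis`` chooses the phenotypic SD entering GA: the SD of entry
    means (``"entry_mean"``, the default, matching selection among entries)
    or the plot-level SD (``"plot"``).
    """
    anova = anova_three_way(ds, trait)
    vc = estimate_varcomps(anova, ds.design)
    H = broad_sense_heritability(vc)
    if sigma_p_basis == "entry_mean":
        em = entry_means(ds, trait)["mean"]
        sigmaP = float(em.std(ddof=1))
    elif sigma_p_basis == "plot":
        sigmaP = float(ds.data[trait].std(ddof=1))
    else:
        raise ValueError("sigma_p_basis must be 'entry_mean' or 'plot'")
    mean = float(ds.data[trait].mean())
    GA = genetic_advance(sigmaP, H, K)
    return GainSummary(
        trait=trait,
        label=label,
        mean=mean,
        sigmaP=sigmaP,
        H_BS=H,
        K=K,
        GA=GA,
        gain_pct=genetic_gain_percent(GA, mean) if mean > 0 else float("nan"),
        gain_over_F5_pct=gain_over_reference(mean, f5_mean) if f5_mean else None,
        gain_over_check_pct=gain_over_reference(mean, check_mean) if check_mean else None,
    )


def per_family_gain_summaries(
    ds: TrialDataset,
    trait: str,
    K: float = 2.06,
    f5_means: dict[str, float] | None = None,
    check_mean: float | None = None,
) -> list[GainSummary]:
    """Run the gain workup separately for every family in the dataset."""
    if "family" not in ds.data.columns:
        raise KeyError("dataset has no 'family' column")
    out = []
    for fam in sorted(ds.data["family"].dropna().unique()):
        sub = ds.subset(family=fam)
        f5 = (f5_means or {}).get(fam)
        out.append(
            gain_summary(
                sub, trait, label=fam, K=K, f5_mean=f5, check_mean=check_mean
            )
        )
    return out
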