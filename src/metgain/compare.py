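"""Population comparisons: t-tests, Dunnett many-to-one, correlations, BLUPs.

Half-sib families from a recurrent-selection program are compared against
the unselected base population and check varieties at the line-mean level:
Welch two-sample t-tests per family, Dunnett's many-to-one procedure for
familywise error control, Pearson correlations among traits computed on
least-squares (adjusted) entry means, and a random-effects yield model
whose progeny BLUPs give a shrinkage ranking of the crossed lines.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .reml import RemlResult, em_reml
from .trial import TrialDataset

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    pvalue: float
    df: float


def mean_shift_ttest(
    group_a: Sequence[float],
    group_b: Sequence[float],
    equal_var: bool = False,
) -> TTestResult:
    """Two-sample t-test on entry means (Welch by default)."""
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 entries")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return TTestResult(float(res.statistic), float(res.pvalue), float(res.df))


def dunnett_many_to_one(
    groups: Sequence[Sequence[float]],
    control: Sequence[float],
    alpha: float = 0.05,
    alternative: str = "two-sided",
    seed: int | None = None,
    labels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Dunnett's many-to-one comparisons against a shared control.

    Adjusted p-values come from the multivariate-t distribution of the
    maximum statistic, integrated by quasi-Monte-Carlo with a fixed seed
    (reproducible; integration error on p is about 1e-3).  The unadjusted
    column is the two-sided p of the same pooled-variance statistic, so
    ``p_adjusted >= p_unadjusted`` up to integration error.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    groups = [np.asarray(g, float) for g in groups]
    control = np.asarray(control, float)
    if len(groups) < 1:
        raise ValueError("need at least one comparison group")
    if any(len(g) < 2 for g in groups) or len(control) < 2:
        raise ValueError("all groups need >= 2 entries")
    if np.var(control, ddof=1) == 0 and all(
        np.var(g, ddof=1) == 0 for g in groups
    ):
        raise ValueError("all groups are constant; test degenerate")
    rng = np.random.default_rng(seed)
    res = stats.dunnett(*groups, control=control, alternative=alternative, rng=rng)
    k = len(groups)
    n_total = sum(len(g) for g in groups) + len(control)
    df = n_total - k - 1
    stat = np.asarray(res.statistic, float)
    if alternative == "two-sided":
        p_unadj = 2 * stats.t.sf(np.abs(stat), df)
    elif alternative == "greater":
        p_unadj = stats.t.sf(stat, df)
    else:
        p_unadj = stats.t.cdf(stat, df)
    if labels is None:
        labels = [f"group{i + 1}" for i in range(k)]
    return pd.DataFrame(
        {
            "group": list(labels),
            "statistic": stat,
            "p_unadjusted": p_unadj,
            "p_adjusted": np.asarray(res.pvalue, float),
            "significant": np.asarray(res.pvalue, float) < alpha,
        }
    )


def adjusted_means(ds: TrialDataset, trait: str) -> pd.Series:
    """Least-squares entry means adjusted for treatment, year, and replicate.

    Fits an additive fixed-effects model entry + treatment + year + rep by
    OLS and averages predictions over the observed levels of the nuisance
    factors.  On balanced data this reduces to the arithmetic entry means.
    Entries with no non-missing plot are dropped with a warning.
    """
    import statsmodels.formula.api as smf

    if trait not in ds.trait_names:
        raise KeyError(f"trait '{trait}' not in dataset")
    d = ds.data[["entry", "treatment", "year", "rep", trait]].dropna(
        subset=[trait]
    )
    dropped = sorted(set(ds.data["entry"]) - set(d["entry"]))
    if dropped:
        logger.warning("entries with no data for %s dropped: %s", trait, dropped)
    d = d.rename(columns={trait: "_y"})
    terms = ["C(entry)"]
    for col in ("treatment", "year", "rep"):
        if d[col].nunique() > 1:
            terms.append(f"C({col})")
    fit = smf.ols("_y ~ " + " + ".join(terms), data=d).fit()
    entries = sorted(d["entry"].unique())
    grid = pd.MultiIndex.from_product(
        [entries, d["treatment"].unique(), d["year"].unique(), d["rep"].unique()],
        names=["entry", "treatment", "year", "rep"],
    ).to_frame(index=False)
    pred = fit.predict(grid)
    out = pred.groupby(grid["entry"]).mean()
    out.name = trait
    return out


@dataclass(frozen=True)
class CorrelationResult:
    r: pd.DataFrame
    p: pd.DataFrame
    significant: pd.DataFrame


def trait_correlations(
    means: pd.DataFrame, alpha: float = 0.05
) -> CorrelationResult:
    """Pearson correlations between traits on per-entry (adjusted) means.

    ``means`` is an entry x trait table (entries as rows).  Two-sided
    t-based p-values; pairs with p < ``alpha`` are flagged significant.
    Constant traits produce missing correlations with a warning.
    """
    if len(means) < 4:
        raise ValueError("need >= 4 entries for trait correlations")
    if means.shape[1] < 2:
        raise ValueError("need >= 2 traits")
    traits = list(means.columns)
    k = len(traits)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    for i in range(k):
        xi = means[traits[i]].to_numpy(float)
        for j in range(i, k):
            xj = means[traits[j]].to_numpy(float)
            ok = ~(np.isnan(xi) | np.isnan(xj))
            if ok.sum() < 4 or np.std(xi[ok]) == 0 or np.std(xj[ok]) == 0:
                if np.std(xi[ok]) == 0 or np.std(xj[ok]) == 0:
                    logger.warning(
                        "constant trait in pair (%s, %s); correlation undefined",
                        traits[i],
                        traits[j],
                    )
                continue
            if i == j:
                r[i, i], p[i, i] = 1.0, 0.0
                continue
            res = stats.pearsonr(xi[ok], xj[ok])
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    idx = pd.Index(traits)
    r_df = pd.DataFrame(r, idx, idx)
    p_df = pd.DataFrame(p, idx, idx)
    return CorrelationResult(r_df, p_df, p_df < alpha)


# ---------------------------------------------------------------------- #
# BLUPs


#: Random terms of the yield model: progeny, treatment, year, replicate
#: nested in treatment-year, and the progeny x treatment / progeny x year
#: interactions.  Only the intercept is fixed.
DEFAULT_BLUP_TERMS = (
    "progeny",
    "treatment",
    "year",
    "rep:treatment:year",
    "progeny:treatment",
    "progeny:year",
)


@dataclass
class BlupModelSpec:
    """Random-effects model specification for progeny BLUPs."""

    response: str = "yield"
    progeny_col: str = "entry"
    random_terms: tuple[str, ...] = DEFAULT_BLUP_TERMS
    tol: float = 1e-6
    maxiter: int = 10000


@dataclass
class BlupResult:
    varcomps: dict[str, float]
    sigma2_e: float
    intercept: float
    blups: pd.Series
    ranking: pd.DataFrame
    reml: RemlResult


def _incidence(codes: pd.Series) -> tuple[np.ndarray, list[str]]:
    levels, inv = np.unique(codes.astype(str).to_numpy(), return_inverse=True)
    Z = np.zeros((len(codes), len(levels)))
    Z[np.arange(len(codes)), inv] = 1.0
    return Z, list(levels)


def fit_blups(ds: TrialDataset, spec: BlupModelSpec | None = None) -> BlupResult:
    """REML variance components and progeny BLUPs for the yield model.

    Progeny effects are predicted with shrinkage toward zero; the ranking
    is descending by BLUP.  Raises
    :class:`~metgain.reml.ConvergenceError` (carrying the last iterate) if
    the EM iteration does not converge.
    """
    spec = spec or BlupModelSpec()
    if spec.response not in ds.trait_names:
        raise KeyError(f"response '{spec.response}' not in dataset")
    d = ds.data.dropna(subset=[spec.response]).copy()
    d["progeny"] = d[spec.progeny_col].astype(str)
    if d["progeny"].nunique() < 2:
        raise ValueError("need >= 2 progenies to fit BLUPs")
    y = d[spec.response].to_numpy(float)

    Zs, names, level_map = [], [], {}
    for term in spec.random_terms:
        cols = term.split(":")
        codes = d[cols[0]].astype(str)
        for c in cols[1:]:
            codes = codes + ":" + d[c].astype(str)
        Z, levels = _incidence(codes)
        Zs.append(Z)
        names.append(term)
        level_map[term] = levels

    res = em_reml(
        y,
        np.ones((len(y), 1)),
        Zs,
        names=names,
        tol=spec.tol,
        maxiter=spec.maxiter,
    )
    blups = pd.Series(
        res.blups["progeny"], index=pd.Index(level_map["progeny"], name="progeny")
    )
    ranking = (
        blups.sort_values(ascending=False)
        .rename("blup")
        .reset_index()
        .assign(rank=lambda f: np.arange(1, len(f) + 1))
    )
    return BlupResult(
        varcomps=res.varcomps,
        sigma2_e=res.sigma2_e,
        intercept=float(res.fixed_effects[0]),
        blups=blups,
        ranking=ranking,
        reml=res,
    )
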