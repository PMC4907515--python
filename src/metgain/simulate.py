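"""Synthetic multi-environment trials and recurrent-selection scenarios.

The generating model mirrors the random-effects decomposition used for
variance-component estimation: a plot value is

    y_ijkl = mu + G_i + T_j + Y_k + GT_ij + GY_ik + GTY_ijk + R_l(jk) + e_ijkl

with genotype main effects and all genotype interactions drawn as
independent Gaussians with the requested variances, treatment and year
shifts supplied as fixed offsets, replicate effects nested within
treatment-year, and i.i.d. residuals.  Selection scenarios layer truncation
selection and a stress-specific yield adjustment on top, producing paired
"base" and "halfsib" populations like those a recurrent-selection program
compares.

All randomness flows through explicit seeds; there is no global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .trial import TREATMENTS, DesignDims, TrialDataset


class ParameterError(ValueError):
    """A simulation parameter violates its constraint."""


@dataclass
class VarCompSpec:
    """Variance components and fixed shifts of the generating model.

    Defaults emulate a rainfed/restricted-irrigation wheat yield trial in
    g/plot: entry means near 550, phenotypic SD of entry means near 100,
    and broad-sense heritability (entry-mean basis, t = y = r = 2) near 30%,
    the regime where stress trials typically operate.
    """

    mu: float = 550.0
    sigma2_G: float = 3000.0
    sigma2_GT: float = 4000.0
    sigma2_GY: float = 4000.0
    sigma2_GTY: float = 2000.0
    sigma2_e: float = 16000.0
    treatment_effects: Mapping[str, float] = field(
        default_factory=lambda: {"RI": 0.0, "RF": 0.0}
    )
    year_effects: Sequence[float] | None = None
    rep_effect_sd: float = 0.0

    def __post_init__(self) -> None:
        for name in ("sigma2_G", "sigma2_GT", "sigma2_GY", "sigma2_GTY", "sigma2_e"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.rep_effect_sd < 0:
            raise ParameterError("rep_effect_sd must be >= 0")


@dataclass
class SelectionScenario:
    """One or more cycles of phenotypic truncation selection.

    ``h2`` is the generating-truth heritability used to translate the
    realized phenotypic selection differential into a genetic shift of the
    offspring mean.  ``stress_yield_ratio_*`` set the target RF/RI mean-yield
    ratio of each population: stress trials commonly see unselected material
    collapse under rainfed conditions while selected material holds its
    yield, and the ratios reproduce that contrast multiplicatively.
    """

    n_base: int = 150
    n_cycles: int = 1
    selection_fraction: float = 0.05
    K: float = 2.06
    h2: float = 0.3
    stress_yield_ratio_base: float = 0.53
    stress_yield_ratio_selected: float = 1.09
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.selection_fraction <= 1):
            raise ParameterError("selection_fraction must lie in (0, 1]")
        if not (0 <= self.h2 <= 1):
            raise ParameterError("h2 must lie in [0, 1]")
        if self.stress_yield_ratio_base <= 0 or self.stress_yield_ratio_selected <= 0:
            raise ParameterError("stress yield ratios must be > 0")
        if self.n_cycles < 0:
            raise ParameterError("n_cycles must be >= 0")
        if self.n_base < 2:
            raise ParameterError("n_base must be >= 2")


def _simulate_frame(
    spec: VarCompSpec,
    dims: DesignDims,
    rng: np.random.Generator,
    genetic_values: np.ndarray | None,
    entry_prefix: str,
    trait: str,
    pop_class: str | None,
) -> pd.DataFrame:
    g, t, y, r = dims.g, dims.t, dims.y, dims.r
    if t > len(TREATMENTS):
        raise ParameterError(f"at most {len(TREATMENTS)} treatments supported")
    treatments = list(TREATMENTS[:t])
    year_eff = (
        np.zeros(y) if spec.year_effects is None else np.asarray(spec.year_effects, float)
    )
    if len(year_eff) != y:
        raise ParameterError("year_effects length must equal dims.y")
    treat_eff = np.array([spec.treatment_effects.get(tr, 0.0) for tr in treatments])

    if genetic_values is None:
        G = rng.normal(0.0, np.sqrt(spec.sigma2_G), g)
    else:
        G = np.asarray(genetic_values, float)
        if len(G) != g:
            raise ParameterError("genetic_values length must equal dims.g")
    GT = rng.normal(0.0, np.sqrt(spec.sigma2_GT), (g, t))
    GY = rng.normal(0.0, np.sqrt(spec.sigma2_GY), (g, y))
    GTY = rng.normal(0.0, np.sqrt(spec.sigma2_GTY), (g, t, y))
    R = rng.normal(0.0, spec.rep_effect_sd, (t, y, r))
    eps = rng.normal(0.0, np.sqrt(spec.sigma2_e), (g, t, y, r))

    value = (
        spec.mu
        + G[:, None, None, None]
        + treat_eff[None, :, None, None]
        + year_eff[None, None, :, None]
        + GT[:, :, None, None]
        + GY[:, None, :, None]
        + GTY[:, :, :, None]
        + R[None, :, :, :]
        + eps
    )

    width = max(3, len(str(g)))
    entries = [f"{entry_prefix}{i + 1:0{width}d}" for i in range(g)]
    idx = pd.MultiIndex.from_product(
        [entries, treatments, range(1, y + 1), range(1, r + 1)],
        names=["entry", "treatment", "year", "rep"],
    )
    flat = value.reshape(-1)
    if trait == "yield":
        # physical yields are non-negative; at the default parameters the
        # Gaussian tail below zero is ~6e-4 so clipping barely moves moments
        flat = np.clip(flat, 0.0, None)
    df = pd.DataFrame({trait: flat}, index=idx).reset_index()
    if pop_class is not None:
        df["pop_class"] = pop_class
    return df


def simulate_met(
    spec: VarCompSpec,
    dims: DesignDims,
    seed: int,
    trait: str = "yield",
    entry_prefix: str = "g",
    pop_class: str | None = None,
) -> TrialDataset:
    """Generate one fully balanced MET dataset.

    Identical ``spec``, ``dims`` and ``seed`` produce identical tables.
    """
    rng = np.random.default_rng(seed)
    df = _simulate_frame(spec, dims, rng, None, entry_prefix, trait, pop_class)
    return TrialDataset(df, [trait])


@dataclass
class SelectionResult:
    """Paired populations from a selection scenario plus diagnostics."""

    base: TrialDataset
    selected: TrialDataset
    genetic_shift: float
    per_cycle_differentials: list[float]


def simulate_selection_response(
    scn: SelectionScenario,
    spec: VarCompSpec,
    dims: DesignDims,
    trait: str = "yield",
) -> SelectionResult:
    """Simulate truncation selection and return base + selected populations.

    Each cycle phenotypes the current population (entry means over all plots
    of a balanced trial at ``dims``), keeps the top ``selection_fraction``,
    and shifts the offspring genetic mean by ``h2`` times the realized
    phenotypic selection differential.  Genetic variance is regenerated each
    cycle (no inbreeding or drift model).  Finally the base and selected
    populations are re-grown side by side and the rainfed plots of each are
    scaled to its target RF/RI yield ratio.
    """
    rng = np.random.default_rng(scn.seed)
    n = scn.n_base
    pheno_dims = DesignDims(g=n, t=dims.t, y=dims.y, r=dims.r)

    base_gv = rng.normal(0.0, np.sqrt(spec.sigma2_G), n)
    gv = base_gv.copy()
    shift = 0.0
    differentials: list[float] = []
    for _ in range(scn.n_cycles):
        df = _simulate_frame(spec, pheno_dims, rng, gv, "c", trait, None)
        means = df.groupby("entry", sort=True)[trait].mean()
        # entry labels are zero-padded, so sorted order matches gv order
        means = means.to_numpy()
        k = int(round(scn.selection_fraction * n))
        if k < 2:
            raise ParameterError(
                f"selection_fraction {scn.selection_fraction} keeps {k} < 2 parents"
            )
        sel = np.argsort(means)[-k:]
        S = means[sel].mean() - means.mean()
        differentials.append(float(S))
        shift += scn.h2 * S
        gv = rng.normal(shift, np.sqrt(spec.sigma2_G), n)

    base_df = _simulate_frame(spec, pheno_dims, rng, base_gv, "b", trait, "base")
    sel_df = _simulate_frame(spec, pheno_dims, rng, gv, "hs", trait, "halfsib")
    base_df.loc[base_df["treatment"] == "RF", trait] *= scn.stress_yield_ratio_base
    sel_df.loc[sel_df["treatment"] == "RF", trait] *= scn.stress_yield_ratio_selected
    return SelectionResult(
        base=TrialDataset(base_df, [trait]),
        selected=TrialDataset(sel_df, [trait]),
        genetic_shift=float(shift),
        per_cycle_differentials=differentials,
    )
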