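"""End-to-end analysis pipeline.

Loads (or simulates) a trial, then runs, per trait: population and family
gain summaries; the drought-index table with ranks on yield; Welch t-tests
and Dunnett many-to-one comparisons of families against the base
population and a check; trait correlations on adjusted means; and progeny
BLUPs.  Every output table is written to the output directory together
with a provenance record (config hash, seed, package version) so a run can
be reproduced byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from .compare import (
    BlupModelSpec,
    dunnett_many_to_one,
    adjusted_means,
    fit_blups,
    mean_shift_ttest,
    trait_correlations,
)
from .indices import index_table_from_dataset
from .simulate import (
    SelectionScenario,
    VarCompSpec,
    simulate_selection_response,
)
from .trial import DesignDims, TrialDataset, entry_means, read_trial_csv, write_table
from .varcomp import gain_summary, per_family_gain_summaries

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid run configuration."""


@dataclass
class RunConfig:
    """Configuration of one pipeline run (YAML/JSON serialisable)."""

    input: str | None = None
    scenario: dict | None = None
    traits: list[str] = field(default_factory=lambda: ["yield"])
    reference_entries: dict = field(default_factory=dict)
    schema: dict | None = None
    treatment_map: dict | None = None
    K: float = 2.06
    alpha: float = 0.05
    equal_var: bool = False
    tie_method: str = "average"
    seed: int = 0
    output_dir: str = "metgain_report"
    log_level: str = "INFO"
    fit_blup: bool = True

    def __post_init__(self) -> None:
        if (self.input is None) == (self.scenario is None):
            raise ConfigError("exactly one of 'input' and 'scenario' must be set")
        if not (0 < self.alpha < 1):
            raise ConfigError("alpha must lie in (0, 1)")
        if not self.traits:
            raise ConfigError("at least one trait required")

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if not isinstance(d, dict):
            raise ConfigError("config file must hold a mapping")
        return cls.from_dict(d)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class ReportBundle:
    """All result tables of one run plus provenance."""

    gain_tables: dict[str, pd.DataFrame]
    index_table: pd.DataFrame | None
    ttest_table: pd.DataFrame | None
    dunnett_table: pd.DataFrame | None
    correlation_table: pd.DataFrame | None
    blup_ranking: pd.DataFrame | None
    provenance: dict
    errors: dict[str, str]
    output_dir: Path


def _load_or_simulate(cfg: RunConfig) -> TrialDataset:
    if cfg.input is not None:
        return read_trial_csv(
            cfg.input, schema=cfg.schema, treatment_map=cfg.treatment_map
        )
    sc = dict(cfg.scenario or {})
    dims = DesignDims(**sc.pop("dims", {"g": 1, "t": 2, "y": 2, "r": 2}))
    spec_kw = sc.pop("varcomp", {})
    scn_kw = sc.pop("selection", {})
    n_families = int(sc.pop("n_families", 10))
    if sc:
        raise ConfigError(f"unknown scenario key(s): {sorted(sc)}")
    scn_kw.setdefault("seed", cfg.seed)
    res = simulate_selection_response(
        SelectionScenario(**scn_kw), VarCompSpec(**spec_kw), dims
    )
    sel = res.selected.data.copy()
    # group selected entries round-robin into pseudo half-sib families
    entries = sorted(sel["entry"].unique())
    fam_of = {
        e: f"hs{(i % n_families) + 1:02d}" for i, e in enumerate(entries)
    }
    sel["family"] = sel["entry"].map(fam_of)
    both = pd.concat([res.base.data, sel], ignore_index=True)
    return TrialDataset(both, res.base.trait_names)


def run_pipeline(cfg: RunConfig) -> ReportBundle:
    """Execute the full analysis described by ``cfg``.

    Per-trait failures (for example an unbalanced layout reaching the
    closed-form ANOVA) are logged and recorded in ``errors`` without
    aborting the remaining traits.
    """
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds = _load_or_simulate(cfg)

    refs = cfg.reference_entries
    errors: dict[str, str] = {}
    gain_tables: dict[str, pd.DataFrame] = {}
    ttest_rows = []
    dunnett_tables = []
    adj_by_trait = {}

    has_base = (
        "pop_class" in ds.data.columns and (ds.data["pop_class"] == "base").any()
    )
    has_hs = (
        "pop_class" in ds.data.columns and (ds.data["pop_class"] == "halfsib").any()
    )

    for trait in cfg.traits:
        try:
            rows = []
            if has_base:
                rows.append(
                    gain_summary(
                        ds.subset(pop_class="base"), trait, "base", K=cfg.K
                    ).as_row()
                )
            if has_hs:
                rows.append(
                    gain_summary(
                        ds.subset(pop_class="halfsib"), trait, "hsib", K=cfg.K
                    ).as_row()
                )
            if "family" in ds.data.columns and ds.data["family"].notna().any():
                rows += [
                    s.as_row()
                    for s in per_family_gain_summaries(ds, trait, K=cfg.K)
                ]
            if not rows:
                rows = [gain_summary(ds, trait, "all", K=cfg.K).as_row()]
            gain_tables[trait] = pd.DataFrame(rows)
        except Exception as exc:  # recorded, not fatal
            logger.error("gain analysis failed for %s: %s", trait, exc)
            errors[f"gain:{trait}"] = str(exc)
        try:
            adj_by_trait[trait] = adjusted_means(ds, trait)
        except Exception as exc:
            errors[f"adjusted_means:{trait}"] = str(exc)

        if has_base and has_hs:
            try:
                base_m = entry_means(ds.subset(pop_class="base"), trait)["mean"]
                hs_m = entry_means(ds.subset(pop_class="halfsib"), trait)["mean"]
                t = mean_shift_ttest(hs_m, base_m, equal_var=cfg.equal_var)
                ttest_rows.append(
                    {
                        "trait": trait,
                        "comparison": "halfsib vs base",
                        "t": t.statistic,
                        "p": t.pvalue,
                    }
                )
            except Exception as exc:
                errors[f"ttest:{trait}"] = str(exc)

    # drought indices on yield
    index_table = None
    yield_trait = "yield" if "yield" in cfg.traits else cfg.traits[0]
    ref_entry = refs.get("index_reference")
    if ref_entry is not None:
        try:
            index_table = index_table_from_dataset(
                ds, ref_entry, trait=yield_trait, ties=cfg.tie_method
            )
        except Exception as exc:
            errors["indices"] = str(exc)

    # Dunnett: families vs base-population control, per trait
    dunnett_table = None
    if has_base and "family" in ds.data.columns:
        fams = sorted(ds.data["family"].dropna().unique())
        if fams:
            for trait in cfg.traits:
                try:
                    ctrl = entry_means(ds.subset(pop_class="base"), trait)["mean"]
                    grps = [
                        entry_means(ds.subset(family=f), trait)["mean"] for f in fams
                    ]
                    tbl = dunnett_many_to_one(
                        grps,
                        ctrl,
                        alpha=cfg.alpha,
                        seed=cfg.seed,
                        labels=fams,
                    )
                    tbl.insert(0, "trait", trait)
                    tbl.insert(1, "control", "base")
                    dunnett_tables.append(tbl)
                except Exception as exc:
                    errors[f"dunnett:{trait}"] = str(exc)
            if dunnett_tables:
                dunnett_table = pd.concat(dunnett_tables, ignore_index=True)

    correlation_table = None
    if len(adj_by_trait) >= 2:
        try:
            mat = pd.DataFrame(adj_by_trait)
            correlation_table = trait_correlations(mat, alpha=cfg.alpha).r
        except Exception as exc:
            errors["correlations"] = str(exc)

    blup_ranking = None
    if cfg.fit_blup:
        try:
            sub = ds.subset(pop_class="halfsib") if has_hs else ds
            blup_ranking = fit_blups(
                sub, BlupModelSpec(response=yield_trait)
            ).ranking
        except Exception as exc:
            errors["blup"] = str(exc)

    provenance = {
        "config": cfg.to_dict(),
        "config_hash": cfg.digest(),
        "seed": cfg.seed,
        "version": __version__,
        "defaults": {
            "K": cfg.K,
            "alpha": cfg.alpha,
            "ttest": "welch" if not cfg.equal_var else "pooled",
            "rank_ties": cfg.tie_method,
        },
        "errors": errors,
    }

    for name, tbl in list(gain_tables.items()):
        write_table(tbl, outdir / f"gain_{name}.csv")
    ttest_table = pd.DataFrame(ttest_rows) if ttest_rows else None
    for name, tbl in (
        ("index_table", index_table),
        ("ttests", ttest_table),
        ("dunnett", dunnett_table),
        ("blup_ranking", blup_ranking),
    ):
        if tbl is not None and not tbl.empty:
            write_table(tbl, outdir / f"{name}.csv")
    if correlation_table is not None:
        correlation_table.to_csv(outdir / "correlations.csv")
    (outdir / "provenance.json").write_text(
        json.dumps(provenance, indent=2, sort_keys=True) + "\n"
    )

    return ReportBundle(
        gain_tables=gain_tables,
        index_table=index_table,
        ttest_table=ttest_table,
        dunnett_table=dunnett_table,
        correlation_table=correlation_table,
        blup_ranking=blup_ranking,
        provenance=provenance,
        errors=errors,
        output_dir=outdir,
    )
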