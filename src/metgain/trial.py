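"""Plot-level trial data containers and tabular I/O.

A multi-environment trial (MET) observation is one plot: an entry (line,
family bulk, parent, or check variety) grown under one irrigation treatment
in one year and replicate, with one or more measured traits.  Treatments are
normalized to ``RI`` (restricted irrigation, the non-stress regime) and
``RF`` (rainfed, the stress regime).  All downstream analyses — variance
components, drought indices, population comparisons — consume the
:class:`TrialDataset` defined here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TREATMENTS = ("RI", "RF")
POP_CLASSES = ("base", "halfsib", "parent", "check")

#: Columns with design meaning; everything else in a trial table is a trait.
FACTOR_COLUMNS = ("entry", "family", "pop_class", "treatment", "year", "rep", "block")

_REQUIRED = ("entry", "treatment", "year", "rep")


class SchemaError(ValueError):
    """A required column is missing or a factor holds an unmapped value."""


class ValidationError(ValueError):
    """Trial records violate a structural invariant (duplicates, bounds)."""


class UnbalancedDataError(ValueError):
    """The genotype x treatment x year x replicate layout is incomplete."""


@dataclass(frozen=True)
class DesignDims:
    """Dimensions of a crossed trial design.

    Attributes
    ----------
    g : number of entries (genotypes)
    t : number of treatments (2 for an RI/RF trial)
    y : number of years
    r : number of replicates per treatment-year
    """

    g: int
    t: int
    y: int
    r: int

    def __post_init__(self) -> None:
        for name in ("g", "t", "y", "r"):
            if getattr(self, name) < 1:
                raise ValueError(f"design dimension {name} must be >= 1")

    @property
    def n_plots(self) -> int:
        return self.g * self.t * self.y * self.r


@dataclass
class TrialRecord:
    """A single plot observation."""

    entry_id: str
    treatment: str
    year: int
    replicate: int
    traits: dict[str, float] = field(default_factory=dict)
    family: str | None = None
    pop_class: str | None = None
    block: int | None = None


def _check_trait_bounds(df: pd.DataFrame) -> None:
    checks = (
        ("yield", lambda s: s < 0, "yield must be >= 0"),
        ("hi", lambda s: (s < 0) | (s > 1), "harvest index must lie in [0, 1]"),
        ("ndvi", lambda s: (s < -1) | (s > 1), "NDVI must lie in [-1, 1]"),
    )
    for col, bad, msg in checks:
        if col in df.columns:
            mask = bad(df[col].astype(float)) & df[col].notna()
            if mask.any():
                rows = df.index[mask].tolist()[:5]
                raise ValidationError(f"{msg}; offending rows {rows}")


class TrialDataset:
    """Validated table of plot observations plus design metadata.

    Parameters
    ----------
    data:
        One row per plot with the factor columns ``entry``, ``treatment``,
        ``year``, ``rep`` (``family``, ``pop_class``, ``block`` optional) and
        one numeric column per trait.
    trait_names:
        Ordered trait columns; defaults to every non-factor column.
    trait_units:
        Optional unit strings carried as metadata, never converted.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        trait_names: Sequence[str] | None = None,
        trait_units: Mapping[str, str] | None = None,
    ) -> None:
        df = data.copy().reset_index(drop=True)
        missing = [c for c in _REQUIRED if c not in df.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        if trait_names is None:
            trait_names = [c for c in df.columns if c not in FACTOR_COLUMNS]
        if not trait_names:
            raise SchemaError("dataset has no trait columns")
        bad_t = sorted(set(df["treatment"].astype(str)) - set(TREATMENTS))
        if bad_t:
            raise SchemaError(
                f"treatment values {bad_t} not in {TREATMENTS}; supply a treatment_map"
            )
        if "pop_class" in df.columns:
            bad_p = sorted(
                set(df["pop_class"].dropna().astype(str)) - set(POP_CLASSES)
            )
            if bad_p:
                raise SchemaError(f"pop_class values {bad_p} not in {POP_CLASSES}")
        df["entry"] = df["entry"].astype(str)
        df["year"] = df["year"].astype(int)
        df["rep"] = df["rep"].astype(int)
        if (df["rep"] < 1).any():
            raise ValidationError("replicate numbers must be >= 1")
        for t in trait_names:
            if t not in df.columns:
                raise SchemaError(f"trait column '{t}' not present")
            df[t] = pd.to_numeric(df[t], errors="raise")

        key = ["entry", "treatment", "year", "rep"]
        dup = df.duplicated(subset=key, keep=False)
        if dup.any():
            offenders = (
                df.loc[dup, key].drop_duplicates().head(10).to_records(index=False)
            )
            raise ValidationError(
                f"duplicate design keys (entry, treatment, year, rep): {list(offenders)}"
            )
        _check_trait_bounds(df)

        self.data = df
        self.trait_names = list(trait_names)
        self.trait_units = dict(trait_units or {})

    # ------------------------------------------------------------------ #

    @property
    def design(self) -> DesignDims:
        d = self.data
        return DesignDims(
            g=d["entry"].nunique(),
            t=d["treatment"].nunique(),
            y=d["year"].nunique(),
            r=d["rep"].nunique(),
        )

    def __len__(self) -> int:
        return len(self.data)

    def records(self) -> list[TrialRecord]:
        out = []
        for _, row in self.data.iterrows():
            out.append(
                TrialRecord(
                    entry_id=row["entry"],
                    treatment=row["treatment"],
                    year=int(row["year"]),
                    replicate=int(row["rep"]),
                    traits={t: row[t] for t in self.trait_names},
                    family=row.get("family"),
                    pop_class=row.get("pop_class"),
                    block=int(row["block"]) if "block" in row and pd.notna(row.get("block")) else None,
                )
            )
        return out

    @classmethod
    def from_records(cls, records: Iterable[TrialRecord]) -> "TrialDataset":
        rows = []
        for r in records:
            row = {
                "entry": r.entry_id,
                "treatment": r.treatment,
                "year": r.year,
                "rep": r.replicate,
            }
            if r.family is not None:
                row["family"] = r.family
            if r.pop_class is not None:
                row["pop_class"] = r.pop_class
            if r.block is not None:
                row["block"] = r.block
            row.update(r.traits)
            rows.append(row)
        return cls(pd.DataFrame(rows))

    def subset(
        self,
        entries: Sequence[str] | None = None,
        family: str | None = None,
        pop_class: str | None = None,
    ) -> "TrialDataset":
        """Restrict to chosen entries / family / population class."""
        d = self.data
        if entries is not None:
            d = d[d["entry"].isin([str(e) for e in entries])]
        if family is not None:
            d = d[d.get("family") == family]
        if pop_class is not None:
            d = d[d.get("pop_class") == pop_class]
        if d.empty:
            raise ValidationError("subset selects no records")
        return TrialDataset(d, self.trait_names, self.trait_units)


# ---------------------------------------------------------------------- #
# I/O


def read_trial_csv(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    treatment_map: Mapping[str, str] | None = None,
    trait_names: Sequence[str] | None = None,
) -> TrialDataset:
    """Read a plot-level trial table from CSV.

    ``schema`` maps canonical column names (``entry``, ``treatment``, ``year``,
    ``rep``, trait names ...) to the column headers actually present in the
    file; unmapped columns keep their header as a trait name.
    ``treatment_map`` translates raw treatment labels to ``RI``/``RF``.
    Non-numeric trait cells become missing values; their count is logged.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"trial CSV not found: {path}")
    raw = pd.read_csv(path)
    if schema:
        rename = {src: dst for dst, src in schema.items()}
        missing = [src for src in rename if src not in raw.columns]
        if missing:
            raise SchemaError(
                f"mapped column(s) absent from {path.name}: {', '.join(missing)}"
            )
        raw = raw.rename(columns=rename)
    missing = [c for c in _REQUIRED if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    if treatment_map:
        raw["treatment"] = raw["treatment"].map(
            lambda v: treatment_map.get(v, v)
        )
    if trait_names is None:
        trait_names = [c for c in raw.columns if c not in FACTOR_COLUMNS]
    n_coerced = 0
    for t in trait_names:
        before = raw[t].notna().sum()
        raw[t] = pd.to_numeric(raw[t], errors="coerce")
        n_coerced += int(before - raw[t].notna().sum())
    if n_coerced:
        logger.warning("%d non-numeric trait cell(s) set to missing", n_coerced)
    return TrialDataset(raw, trait_names)


def write_trial_csv(ds: TrialDataset, path: str | Path) -> Path:
    """Write a dataset back to CSV so that re-reading round-trips it."""
    path = Path(path)
    ds.data.to_csv(path, index=False)
    return path


def _to_markdown(df: pd.DataFrame) -> str:
    cols = [str(c) for c in df.columns]
    body = df.astype(object).where(df.notna(), "").astype(str).values.tolist()
    widths = [
        max(len(cols[j]), *(len(row[j]) for row in body)) if body else len(cols[j])
        for j in range(len(cols))
    ]
    def fmt(cells):
        return "| " + " | ".join(c.ljust(w) for c, w in zip(cells, widths)) + " |"
    lines = [fmt(cols), "| " + " | ".join("-" * w for w in widths) + " |"]
    lines += [fmt(row) for row in body]
    return "\n".join(lines) + "\n"


def write_table(
    rows: pd.DataFrame, path: str | Path, format: str = "csv"
) -> Path:
    """Write a result table as CSV, TSV, or a GitHub-style markdown table."""
    if not isinstance(rows, pd.DataFrame):
        rows = pd.DataFrame(rows)
    if rows.empty:
        raise ValueError("refusing to write an empty table")
    path = Path(path)
    if format == "csv":
        rows.to_csv(path, index=False)
    elif format == "tsv":
        rows.to_csv(path, index=False, sep="\t")
    elif format == "markdown":
        path.write_text(_to_markdown(rows))
    else:
        raise ValueError(f"unknown table format: {format!r}")
    return path


# ---------------------------------------------------------------------- #
# Means


_GROUPABLE = ("entry", "family", "pop_class", "treatment", "year")


def entry_means(
    ds: TrialDataset,
    trait: str,
    group_by: Sequence[str] = ("entry",),
) -> pd.DataFrame:
    """Arithmetic group means of one trait over non-missing plots.

    Returns a frame with the grouping columns plus ``mean`` and ``n`` (the
    count of non-missing plots entering each mean).
    """
    if trait not in ds.trait_names:
        raise KeyError(f"trait '{trait}' not in dataset (has {ds.trait_names})")
    bad = [g for g in group_by if g not in _GROUPABLE]
    if bad:
        raise ValueError(f"cannot group by {bad}; allowed: {_GROUPABLE}")
    d = ds.data
    grouped = d.groupby(list(group_by), sort=True, dropna=False)[trait]
    out = grouped.agg(mean="mean", n="count").reset_index()
    out["n"] = out["n"].astype(int)
    return out
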