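"""Yield-based drought-tolerance indices and entry rankings.

Six classical indices contrast an entry's mean yield under stress (rainfed,
``Yi_s``) and non-stress (restricted irrigation, ``Yi_ns``), the normalized
ones dividing by population reference means ``Y_s`` and ``Y_ns``:

    TOL = Yi_ns - Yi_s                    (smaller / negative = more tolerant)
    MPI = (Yi_ns + Yi_s) / 2
    GMP = sqrt(Yi_s * Yi_ns)
    MRP = Yi_s / Y_s + Yi_ns / Y_ns
    REI = (Yi_s / Y_s) * (Yi_ns / Y_ns)
    STI = Yi_ns * Yi_s / Y_ns**2

For every index except TOL a larger value is better; TOL is ranked
ascending because a negative TOL means the entry out-yields itself under
stress.  By the AM-GM inequality GMP <= MPI always, with equality only when
the two yields coincide, and REI <= (MRP / 2)**2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .trial import TrialDataset, entry_means

INDEX_NAMES = ("TOL", "MPI", "GMP", "MRP", "REI", "STI")

#: Indices where smaller values indicate more tolerance (ranked ascending).
_ASCENDING = frozenset({"TOL"})


@dataclass(frozen=True)
class IndexInputs:
    """Mean yields of one entry plus the population reference means.

    ``yi_s`` / ``yi_ns``: entry mean yield under stress (RF) / non-stress
    (RI); ``y_s`` / ``y_ns``: the corresponding reference means (g/plot).
    """

    entry_id: str
    yi_s: float
    yi_ns: float
    y_s: float
    y_ns: float

    def __post_init__(self) -> None:
        if self.yi_s < 0 or self.yi_ns < 0:
            raise ValueError("entry yields must be >= 0")
        if self.y_s <= 0 or self.y_ns <= 0:
            raise ValueError("reference means must be > 0")


def tol(x: IndexInputs) -> float:
    """Stress tolerance: non-stress minus stress yield (g/plot)."""
    return x.yi_ns - x.yi_s


def mpi(x: IndexInputs) -> float:
    """Mean productivity: arithmetic mean of the two yields (g/plot)."""
    return (x.yi_ns + x.yi_s) / 2.0


def gmp(x: IndexInputs) -> float:
    """Geometric mean productivity (g/plot)."""
    return float(np.sqrt(x.yi_s * x.yi_ns))


def mrp(x: IndexInputs) -> float:
    """Mean relative performance: sum of the two yield ratios."""
    return x.yi_s / x.y_s + x.yi_ns / x.y_ns


def rei(x: IndexInputs) -> float:
    """Relative efficiency index: product of the two yield ratios."""
    return (x.yi_s / x.y_s) * (x.yi_ns / x.y_ns)


def sti(x: IndexInputs) -> float:
    """Stress tolerance index: Yi_ns * Yi_s / Y_ns**2."""
    return x.yi_ns * x.yi_s / x.y_ns**2


_INDEX_FUNCS = {"TOL": tol, "MPI": mpi, "GMP": gmp, "MRP": mrp, "REI": rei, "STI": sti}


def _resolve_reference(
    means: pd.DataFrame, reference: str | tuple[float, float]
) -> tuple[float, float]:
    if isinstance(reference, str):
        row = means[means["entry"] == reference]
        if row.empty:
            raise KeyError(f"reference entry '{reference}' not in table")
        return float(row["y_rf"].iloc[0]), float(row["y_ri"].iloc[0])
    y_s, y_ns = reference
    return float(y_s), float(y_ns)


def compute_index_table(
    means: pd.DataFrame,
    reference: str | tuple[float, float],
    ties: str = "average",
) -> pd.DataFrame:
    """All six indices plus per-index ranks for a table of entry means.

    Parameters
    ----------
    means:
        Frame with columns ``entry``, ``y_rf`` (stress mean yield) and
        ``y_ri`` (non-stress mean yield), one row per entry.
    reference:
        Entry id whose yields serve as the reference means, or an explicit
        ``(Y_s, Y_ns)`` pair.
    ties:
        Rank tie policy: ``"average"`` (default) or ``"competition"``
        (minimum rank shared).

    Rank 1 is the most drought-tolerant entry under each index: ascending
    order for TOL, descending for the rest.
    """
    required = {"entry", "y_rf", "y_ri"}
    if not required.issubset(means.columns):
        raise KeyError(f"means table needs columns {sorted(required)}")
    if means.empty:
        raise ValueError("means table is empty")
    if means["entry"].duplicated().any():
        raise ValueError("duplicate entries in means table")
    y_s, y_ns = _resolve_reference(means, reference)
    method = {"average": "average", "competition": "min"}.get(ties)
    if method is None:
        raise ValueError("ties must be 'average' or 'competition'")

    out = means[["entry", "y_rf", "y_ri"]].copy().reset_index(drop=True)
    inputs = [
        IndexInputs(str(e), yi_s=s, yi_ns=ns, y_s=y_s, y_ns=y_ns)
        for e, s, ns in zip(out["entry"], out["y_rf"], out["y_ri"])
    ]
    for name in INDEX_NAMES:
        f = _INDEX_FUNCS[name]
        vals = np.array([f(x) for x in inputs])
        out[name] = vals
        keyed = vals if name in _ASCENDING else -vals
        out[f"rank_{name}"] = stats.rankdata(keyed, method=method)
    return out


def index_table_from_dataset(
    ds: TrialDataset,
    reference: str | tuple[float, float],
    trait: str = "yield",
    ties: str = "average",
) -> pd.DataFrame:
    """Compute the index table straight from plot data.

    Entry means per treatment are taken first; the dataset must contain both
    RI and RF plots for every entry.
    """
    em = entry_means(ds, trait, group_by=("entry", "treatment"))
    wide = em.pivot(index="entry", columns="treatment", values="mean")
    if not {"RI", "RF"}.issubset(wide.columns):
        raise ValueError("dataset must contain both RI and RF observations")
    missing = wide[wide.isna().any(axis=1)].index.tolist()
    if missing:
        raise ValueError(f"entries lacking one treatment: {missing[:10]}")
    means = (
        wide.reset_index()
        .rename(columns={"RF": "y_rf", "RI": "y_ri"})
        .rename_axis(None, axis=1)
    )
    return compute_index_table(means[["entry", "y_rf", "y_ri"]], reference, ties)


def index_correlations(
    table: pd.DataFrame, indices: Sequence[str] = INDEX_NAMES
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlations (and two-sided p-values) between index columns.

    Requires at least 3 entries.  Constant columns yield missing
    correlations rather than an error.
    """
    missing = [c for c in indices if c not in table.columns]
    if missing:
        raise KeyError(f"index column(s) absent: {missing}")
    n = len(table)
    if n < 3:
        raise ValueError(f"need >= 3 entries for correlations, got {n}")
    k = len(indices)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    cols = [table[c].to_numpy(float) for c in indices]
    for i in range(k):
        for j in range(i, k):
            xi, xj = cols[i], cols[j]
            if np.std(xi) == 0 or np.std(xj) == 0:
                continue
            if i == j:
                r[i, j] = 1.0
                p[i, j] = 0.0
                continue
            res = stats.pearsonr(xi, xj)
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    idx = pd.Index(indices)
    return pd.DataFrame(r, idx, idx), pd.DataFrame(p, idx, idx)
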