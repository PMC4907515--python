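"""Independent brute-force oracles used by the tests.

The ANOVA oracle fits the nested sequence of linear models

    1 -> +G -> +T -> +Y -> +GT -> +GY -> +TY -> +GTY -> +R(TY)

by exact rational least squares (full-rank drop-first dummy coding, normal
equations solved by Fraction Gaussian elimination) and reports each term's
sum of squares as the drop in residual sum of squares.  On balanced data
this sequential decomposition is orthogonal, so it must agree with any
correct balanced ANOVA — but it shares no code or algebra with the
implementation under test, which works from marginal means.
"""

from __future__ import annotations

import itertools
from fractions import Fraction

import pandas as pd


def _solve_exact(A: list[list[Fraction]], b: list[Fraction]) -> list[Fraction]:
    """Gaussian elimination with exact rationals; A must be nonsingular."""
    n = len(A)
    M = [row[:] + [b[i]] for i, row in enumerate(A)]
    for col in range(n):
        piv = next(r for r in range(col, n) if M[r][col] != 0)
        M[col], M[piv] = M[piv], M[col]
        inv = Fraction(1, 1) / M[col][col]
        M[col] = [v * inv for v in M[col]]
        for r in range(n):
            if r != col and M[r][col] != 0:
                f = M[r][col]
                M[r] = [a - f * c for a, c in zip(M[r], M[col])]
    return [M[i][n] for i in range(n)]


def _rss(X: list[list[Fraction]], y: list[Fraction]) -> Fraction:
    p = len(X[0])
    XtX = [
        [sum(X[i][a] * X[i][b] for i in range(len(y))) for b in range(p)]
        for a in range(p)
    ]
    Xty = [sum(X[i][a] * y[i] for i in range(len(y))) for a in range(p)]
    beta = _solve_exact(XtX, Xty)
    return sum(
        (y[i] - sum(X[i][a] * beta[a] for a in range(p))) ** 2
        for i in range(len(y))
    )


def _dummies(values, levels):
    """Drop-first 0/1 coding of one factor observation."""
    return [Fraction(1) if values == lv else Fraction(0) for lv in levels[1:]]


def exact_anova(df: pd.DataFrame, trait: str = "y") -> dict[str, Fraction]:
    """Exact sequential ANOVA of a balanced entry x treatment x year x rep
    table.  Returns sums of squares (Fractions) keyed like the package's
    ANOVA sources."""
    ent = sorted(df["entry"].unique())
    trt = sorted(df["treatment"].unique())
    yrs = sorted(df["year"].unique())
    reps = sorted(df["rep"].unique())
    y = [Fraction(v).limit_denominator(10**12) for v in df[trait]]

    rows = list(df.itertuples(index=False))
    ecol = [r.entry for r in rows]
    tcol = [r.treatment for r in rows]
    ycol = [r.year for r in rows]
    rcol = [r.rep for r in rows]

    def cross(levels_a, vals_a, levels_b, vals_b):
        # drop-first coding of an interaction: products of main dummies
        out = []
        for i in range(len(rows)):
            da = _dummies(vals_a[i], levels_a)
            db = _dummies(vals_b[i], levels_b)
            out.append([a * b for a in da for b in db])
        return out

    def cross3(la, va, lb, vb, lc, vc):
        out = []
        for i in range(len(rows)):
            da = _dummies(va[i], la)
            db = _dummies(vb[i], lb)
            dc = _dummies(vc[i], lc)
            out.append([a * b * c for a in da for b in db for c in dc])
        return out

    blocks = {
        "genotype": [_dummies(e, ent) for e in ecol],
        "treatment": [_dummies(t, trt) for t in tcol],
        "year": [_dummies(v, yrs) for v in ycol],
        "genotype:treatment": cross(ent, ecol, trt, tcol),
        "genotype:year": cross(ent, ecol, yrs, ycol),
        "treatment:year": cross(trt, tcol, yrs, ycol),
        "genotype:treatment:year": cross3(ent, ecol, trt, tcol, yrs, ycol),
    }
    # replicate nested in treatment-year: one drop-first rep dummy set per
    # treatment-year cell
    rep_cols = []
    cells = list(itertools.product(trt, yrs))
    for i in range(len(rows)):
        row = []
        for ct, cy in cells:
            inside = tcol[i] == ct and ycol[i] == cy
            row.extend(
                Fraction(1) if inside and rcol[i] == rv else Fraction(0)
                for rv in reps[1:]
            )
        rep_cols.append(row)
    blocks["rep(treatment:year)"] = rep_cols

    X = [[Fraction(1)] for _ in rows]
    rss_prev = _rss(X, y)
    grand = sum(y) / len(y)
    ss_total = sum((v - grand) ** 2 for v in y)
    out: dict[str, Fraction] = {"total": ss_total}
    for name, cols in blocks.items():
        X = [xi + cols[i] for i, xi in enumerate(X)]
        rss_now = _rss(X, y)
        out[name] = rss_prev - rss_now
        rss_prev = rss_now
    out["residual"] = rss_prev
    return out


def exact_varcomps(
    ss: dict[str, Fraction], g: int, t: int, y: int, r: int
) -> dict[str, Fraction]:
    """Expected-mean-squares solution from the oracle's sums of squares."""
    ms = {
        "genotype": ss["genotype"] / (g - 1),
        "genotype:treatment": ss["genotype:treatment"] / ((g - 1) * (t - 1)),
        "genotype:year": ss["genotype:year"] / ((g - 1) * (y - 1)),
        "genotype:treatment:year": ss["genotype:treatment:year"]
        / ((g - 1) * (t - 1) * (y - 1)),
        "residual": ss["residual"] / ((g - 1) * t * y * (r - 1)),
    }
    return {
        "sigma2_e": ms["residual"],
        "sigma2_GTY": (ms["genotype:treatment:year"] - ms["residual"]) / r,
        "sigma2_GY": (ms["genotype:year"] - ms["genotype:treatment:year"]) / (r * t),
        "sigma2_GT": (ms["genotype:treatment"] - ms["genotype:treatment:year"]) / (r * y),
        "sigma2_G": (
            ms["genotype"]
            - ms["genotype:treatment"]
            - ms["genotype:year"]
            + ms["genotype:treatment:year"]
        )
        / (r * t * y),
    }


def brute_force_ranks(values, ascending, policy="average"):
    """Rank by exhaustive pairwise comparison (oracle for rank ties)."""
    n = len(values)
    ranks = []
    for i in range(n):
        if ascending:
            less = sum(1 for j in range(n) if values[j] < values[i])
            equal = sum(1 for j in range(n) if values[j] == values[i])
        else:
            less = sum(1 for j in range(n) if values[j] > values[i])
            equal = sum(1 for j in range(n) if values[j] == values[i])
        if policy == "average":
            ranks.append(less + (equal + 1) / 2)
        else:  # competition
            ranks.append(less + 1)
    return ranks
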