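"""EM-REML for variance-component models with independent random terms.

Fits y = X b + sum_c Z_c u_c + e with u_c ~ N(0, sigma2_c I) and
e ~ N(0, sigma2_e I) by expectation-maximisation on the restricted
likelihood, solving Henderson's mixed-model equations at each step.  EM is
slower than average-information updates but every accepted iterate keeps
the variance components non-negative and the restricted log-likelihood
non-decreasing, which makes the fit easy to audit.

Convergence is declared when the restricted log-likelihood improves by less
than ``tol`` between checks.  EM approaches a boundary (a component whose
REML maximum is zero) only sublinearly, so when the likelihood plateaus,
any component that is tiny relative to the total variance is tested at
exactly zero and pinned there if the restricted likelihood does not drop —
the analogue of a "singular fit" in other mixed-model software.  Hitting
``maxiter`` first raises :class:`ConvergenceError` carrying the last
iterate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class ConvergenceError(RuntimeError):
    """REML iteration failed to converge; carries the last iterate."""

    def __init__(self, msg: str, result: "RemlResult"):
        super().__init__(msg)
        self.result = result


@dataclass
class RemlResult:
    """Variance components, fixed effects, and BLUPs from one REML fit."""

    varcomps: dict[str, float]
    sigma2_e: float
    fixed_effects: np.ndarray
    blups: dict[str, np.ndarray]
    loglik: float
    n_iter: int
    converged: bool
    loglik_trace: list[float] = field(default_factory=list)


def _reml_loglik(
    y: np.ndarray, X: np.ndarray, Zs: list[np.ndarray], s2: np.ndarray, se: float
) -> float:
    n = len(y)
    V = se * np.eye(n)
    for Z, s in zip(Zs, s2):
        if s > 0:
            V += s * (Z @ Z.T)
    sign, logdet_v = np.linalg.slogdet(V)
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    sign2, logdet_x = np.linalg.slogdet(XtViX)
    beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
    resid = y - X @ beta
    quad = resid @ Vi @ resid
    p = X.shape[1]
    return -0.5 * (
        logdet_v + logdet_x + quad + (n - p) * np.log(2 * np.pi)
    )


def em_reml(
    y: np.ndarray,
    X: np.ndarray,
    Zs: list[np.ndarray],
    names: list[str] | None = None,
    tol: float = 1e-6,
    maxiter: int = 10000,
    check_every: int = 10,
    pin_frac: float = 1e-3,
) -> RemlResult:
    """Fit the variance-component model by EM-REML.

    Parameters
    ----------
    y, X, Zs:
        Response, fixed-effect design (typically a column of ones), and one
        0/1 incidence matrix per random term.
    names:
        Labels for the random terms (defaults to ``vc0`` ...).
    tol:
        Convergence tolerance on the restricted log-likelihood change
        between checks (every ``check_every`` iterations).
    pin_frac:
        Once the likelihood plateaus, a component below ``pin_frac`` times
        the total variance is pinned to zero if that does not lower the
        restricted likelihood by more than ``tol``.
    """
    y = np.asarray(y, float)
    X = np.atleast_2d(np.asarray(X, float))
    n, p = X.shape
    if names is None:
        names = [f"vc{i}" for i in range(len(Zs))]
    if len(names) != len(Zs):
        raise ValueError("names and Zs length mismatch")
    q = [Z.shape[1] for Z in Zs]
    W = np.hstack([X] + list(Zs))
    WtW = W.T @ W
    Wty = W.T @ y
    offs = np.concatenate([[p], p + np.cumsum(q)])

    var0 = float(np.var(y, ddof=1)) or 1.0
    s2 = np.full(len(Zs), var0 / (len(Zs) + 1))
    se = var0 / (len(Zs) + 1)
    active = np.ones(len(Zs), bool)

    trace: list[float] = []
    ll_old = -np.inf
    sol = np.zeros(W.shape[1])
    converged = False
    it = 0
    for it in range(1, maxiter + 1):
        C = WtW.copy()
        for c in range(len(Zs)):
            sl = slice(offs[c], offs[c + 1])
            lam = se / s2[c] if active[c] and s2[c] > 0 else 1e12
            C[sl, sl] += lam * np.eye(q[c])
        Cinv = np.linalg.inv(C)
        sol = Cinv @ Wty
        new_s2 = s2.copy()
        for c in range(len(Zs)):
            if not active[c]:
                new_s2[c] = 0.0
                continue
            sl = slice(offs[c], offs[c + 1])
            uc = sol[sl]
            new_s2[c] = (uc @ uc + se * np.trace(Cinv[sl, sl])) / q[c]
        new_se = (y @ y - sol @ Wty) / (n - p)
        s2, se = new_s2, float(new_se)
        if it % check_every == 0 or it == 1:
            ll = _reml_loglik(y, X, Zs, s2, se)
            trace.append(ll)
            diff = ll - ll_old
            if diff < 100 * tol:
                # plateau: try pinning near-zero components to the boundary
                total = se + s2.sum()
                pinned = False
                for c in np.argsort(s2):
                    if not active[c] or s2[c] >= pin_frac * total:
                        continue
                    s2_trial = s2.copy()
                    s2_trial[c] = 0.0
                    ll_trial = _reml_loglik(y, X, Zs, s2_trial, se)
                    if ll_trial >= ll - tol:
                        s2 = s2_trial
                        active[c] = False
                        ll = ll_trial
                        pinned = True
                if not pinned and diff < tol:
                    converged = True
                    ll_old = ll
                    break
            ll_old = ll

    ll_final = _reml_loglik(y, X, Zs, s2, se)
    blups = {
        nm: sol[offs[c] : offs[c + 1]].copy() for c, nm in enumerate(names)
    }
    result = RemlResult(
        varcomps={nm: float(v) for nm, v in zip(names, s2)},
        sigma2_e=se,
        fixed_effects=sol[:p].copy(),
        blups=blups,
        loglik=float(ll_final),
        n_iter=it,
        converged=converged,
        loglik_trace=trace,
    )
    if not converged:
        raise ConvergenceError(
            f"EM-REML did not converge in {maxiter} iterations "
            f"(last components {result.varcomps}, sigma2_e {se:.6g})",
            result,
        )
    return result
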