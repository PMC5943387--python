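"""Shared nonlinear least-squares machinery for the batch and column fits.

Parameters are optimized in natural-log space (which enforces positivity),
optionally from multiple Latin-hypercube starting points to avoid local
optima.  Standard errors come from the Gauss-Newton approximation
cov = s² (JᵀJ)⁻¹ evaluated at the optimum, propagated back to the linear
scale by the delta method (se_p = p · se_log).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import optimize
from scipy.stats import qmc

__all__ = ["FitResult", "fit_least_squares"]

# Jacobian condition number above which the free set is flagged as
# practically non-identifiable.
_RANK_COND_LIMIT = 1e8


@dataclass
class FitResult:
    """Point estimates, uncertainties and diagnostics of one calibration."""

    estimates: dict[str, float]
    std_errors: dict[str, float]
    objective: float
    converged: bool
    residuals: dict[str, np.ndarray] = field(default_factory=dict)
    identifiable: bool = True
    n_obs: int = 0
    message: str = ""

    def to_dict(self) -> dict:
        return {
            "estimates": dict(self.estimates),
            "std_errors": dict(self.std_errors),
            "objective": float(self.objective),
            "converged": bool(self.converged),
            "identifiable": bool(self.identifiable),
            "n_obs": int(self.n_obs),
            "message": self.message,
        }


class FitError(RuntimeError):
    """Raised when the optimizer fails to converge from every start."""


def fit_least_squares(
    residual_fn: Callable[[dict[str, float]], np.ndarray],
    free_names: Sequence[str],
    init_guess: dict[str, float],
    *,
    n_starts: int = 8,
    seed: int = 0,
    spread_decades: float = 1.0,
    xtol: float = 1e-10,
    max_nfev: int | None = None,
    diff_step: float = 1e-6,
    split_residuals: Callable[[np.ndarray], dict[str, np.ndarray]] | None = None,
) -> FitResult:
    """Minimize ||residual_fn(params)||² over the named free parameters.

    Parameters
    ----------
    residual_fn
        Maps a {name: value} dict (linear scale) to a residual vector.
    free_names
        Parameters to optimize; every name must be in ``init_guess``.
    init_guess
        Starting values (linear scale, > 0).
    n_starts
        Number of starting points: the init guess itself plus
        ``n_starts - 1`` Latin-hypercube points spread ``spread_decades``
        decades around it.  Ties between equally good optima are broken by
        the lower objective, then lexicographically smaller parameter vector.
    """
    free_names = list(free_names)
    for name in free_names:
        if name not in init_guess or not init_guess[name] > 0:
            raise ValueError(f"init_guess must provide a positive value for {name!r}")

    log0 = np.log(np.array([init_guess[n] for n in free_names]))
    # Box in log space: 4 decades either side of the initial guess keeps
    # the optimizer out of regions where the forward model degenerates.
    bound_span = 4.0 * np.log(10.0)
    lo, hi = log0 - bound_span, log0 + bound_span
    n_res: list[int] = []

    def log_residual(theta: np.ndarray) -> np.ndarray:
        values = dict(init_guess)
        values.update({n: float(v) for n, v in zip(free_names, np.exp(theta))})
        try:
            r = np.asarray(residual_fn(values), dtype=float)
        except Exception:
            if not n_res:
                raise
            return np.full(n_res[0], 1e6)
        if not n_res:
            n_res.append(len(r))
        # Guard against solver blow-ups at extreme parameter draws.
        return np.where(np.isfinite(r), r, 1e6)

    starts = [log0]
    if n_starts > 1:
        sampler = qmc.LatinHypercube(d=len(free_names), seed=seed)
        unit = sampler.random(n_starts - 1)
        span = spread_decades * np.log(10.0)
        starts.extend(log0 + (2.0 * unit - 1.0) * span)

    best: optimize.OptimizeResult | None = None
    best_key: tuple | None = None
    for theta0 in starts:
        try:
            sol = optimize.least_squares(
                log_residual, np.clip(theta0, lo, hi), method="trf",
                bounds=(lo, hi), xtol=xtol, max_nfev=max_nfev, diff_step=diff_step,
            )
        except Exception:
            continue
        key = (sol.cost, tuple(np.round(sol.x, 10)))
        if best_key is None or key < best_key:
            best, best_key = sol, key

    if best is None:
        raise FitError("optimizer failed to converge from every starting point")

    theta_hat = best.x
    p_hat = {n: float(v) for n, v in zip(free_names, np.exp(theta_hat))}
    r_hat = best.fun
    J = best.jac
    m, p = J.shape
    dof = max(m - p, 1)
    s2 = 2.0 * best.cost / dof

    sv = np.linalg.svd(J, compute_uv=False)
    identifiable = bool(sv[-1] > 0 and sv[0] / sv[-1] < _RANK_COND_LIMIT)
    if identifiable:
        cov_log = s2 * np.linalg.inv(J.T @ J)
        se_log = np.sqrt(np.maximum(np.diag(cov_log), 0.0))
    else:
        cov_log = s2 * np.linalg.pinv(J.T @ J)
        se_log = np.sqrt(np.maximum(np.diag(cov_log), 0.0))

    std_errors = {n: float(p_hat[n] * se) for n, se in zip(free_names, se_log)}
    residuals = split_residuals(r_hat) if split_residuals is not None else {"all": r_hat}

    values = dict(init_guess)
    values.update(p_hat)
    return FitResult(
        estimates={n: values[n] for n in free_names},
        std_errors=std_errors,
        objective=float(best.cost),
        converged=bool(best.success),
        residuals=residuals,
        identifiable=identifiable,
        n_obs=m,
        message=str(best.message),
    )
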