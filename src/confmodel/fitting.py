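"""Shared least-squares machinery: multistart driver and FitResult container.

All nonlinear fits in this package run in log-parameter space (positivity,
wide dynamic range) through :func:`scipy.optimize.least_squares`, with a
seeded multistart loop and Gauss-Newton covariance for uncertainties.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = ["FitResult", "FitError", "multistart_least_squares"]


class FitError(RuntimeError):
    """Fit failed to converge after multistart; carries residual diagnostics."""


@dataclass
class FitResult:
    """Point estimates with uncertainties and fit provenance.

    ``params``/``stderr`` are in natural (linear) units.  ``flags`` collects
    identifiability and convergence warnings; an empty list means clean.
    """

    params: dict[str, float]
    stderr: dict[str, float]
    cost: float
    residuals: np.ndarray
    n_obs: int
    n_free: int
    converged: bool
    n_starts: int = 1
    seed: int | None = None
    start_costs: list[float] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)
    extra: dict = field(default_factory=dict)

    @property
    def rmsd(self) -> float:
        return float(np.sqrt(np.mean(self.residuals**2))) if self.n_obs else 0.0

    def ci(self, name: str, n_sigma: float = 2.0) -> tuple[float, float]:
        """Symmetric-in-log confidence interval (params are log-fitted)."""
        p, s = self.params[name], self.stderr[name]
        if not np.isfinite(s) or p <= 0:
            return (np.nan, np.nan)
        rel = n_sigma * s / p
        return (p * np.exp(-rel), p * np.exp(rel))

    def summary_rows(self) -> list[dict]:
        return [
            {"parameter": k, "value": v, "stderr": self.stderr.get(k, np.nan)}
            for k, v in sorted(self.params.items())
        ]


def _covariance_stderr(res, n_obs: int) -> np.ndarray:
    """Gauss-Newton stderr of the fitted (log-space) parameters."""
    J = res.jac
    dof = max(n_obs - J.shape[1], 1)
    s2 = 2.0 * res.cost / dof
    try:
        cov = np.linalg.pinv(J.T @ J) * s2
        return np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        return np.full(J.shape[1], np.nan)


def multistart_least_squares(
    residual_fn: Callable[[np.ndarray], np.ndarray],
    x0_log: np.ndarray,
    n_starts: int = 16,
    seed: int | None = 0,
    spread: float = 2.0,
    bounds_log: tuple[np.ndarray, np.ndarray] | None = None,
    xtol: float = 1e-10,
    ftol: float = 1e-10,
    explore_nfev_per_param: int = 30,
    diff_step: float = 1e-4,
) -> tuple[np.ndarray, object, list[float]]:
    """Run least_squares from ``n_starts`` log-space starting points.

    Starts are ``x0_log`` plus log-uniform jitter in [-spread, +spread]
    (natural log; spread=ln(100)/2 covers the spec's 1e-2..1e2 factor range
    at spread≈4.6).  Two stages: every start is explored with a capped
    function-evaluation budget, then the best is refined to full tolerance.
    Returns (best_x_log, best_result, all_costs).
    """
    rng = np.random.default_rng(seed)
    x0_log = np.asarray(x0_log, dtype=float)
    if bounds_log is None:
        bounds_log = (x0_log - 12.0, x0_log + 12.0)
    starts = [x0_log]
    for _ in range(max(n_starts - 1, 0)):
        jit = rng.uniform(-spread, spread, size=x0_log.shape)
        starts.append(np.clip(x0_log + jit, bounds_log[0], bounds_log[1]))

    explore_cap = max(explore_nfev_per_param * len(x0_log), 60)
    best = None
    costs: list[float] = []
    for s in starts:
        try:
            r = least_squares(
                residual_fn,
                s,
                bounds=bounds_log,
                xtol=1e-6,
                ftol=1e-6,
                diff_step=diff_step,
                max_nfev=explore_cap if len(starts) > 1 else None,
            )
        except Exception:
            costs.append(np.inf)
            continue
        costs.append(float(r.cost))
        if best is None or r.cost < best.cost:
            best = r
    if best is None:
        raise FitError("all multistart attempts failed")
    try:  # refine the winning start to full tolerance
        refined = least_squares(
            residual_fn, best.x, bounds=bounds_log, xtol=xtol, ftol=ftol,
            diff_step=diff_step,
        )
        if refined.cost <= best.cost:
            best = refined
    except Exception:
        pass
    return best.x, best, costs


def stderr_linear_from_log(res, values: Sequence[float], n_obs: int) -> np.ndarray:
    """Map log-space stderr to linear scale: sd(p) ≈ p * sd(log p)."""
    sd_log = _covariance_stderr(res, n_obs)
    return np.asarray(values, dtype=float) * sd_log
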