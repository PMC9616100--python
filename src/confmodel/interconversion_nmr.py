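"""Slow two-state conformational exchange from NMR-style observables.

In slow exchange each conformer gives its own resonance, so the inactive
population is read directly from duplicated-peak volumes.  A pH jump
perturbs the equilibrium and the relaxation back is single-exponential with
rate k_obs = k_ina->act + k_act->ina; combined with the equilibrium
populations this splits k_obs into the two microscopic rate constants.
A two-point van't Hoff analysis interpolates populations between
temperatures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .fitting import FitResult, stderr_linear_from_log
from .scheme_core import SchemeValidationError, TimeSeries

__all__ = [
    "PeakPairVolumes",
    "RelaxationSeries",
    "NoRelaxationError",
    "population_from_volumes",
    "aggregate_populations",
    "integrate_peak",
    "fit_relaxation",
    "activation_rate",
    "vant_hoff_shift",
    "VantHoffResult",
]

R_GAS = 8.31446261815324  # J / (mol K)


class NoRelaxationError(RuntimeError):
    """Relaxation fit found no rate distinguishable from zero."""


@dataclass(frozen=True)
class PeakPairVolumes:
    """Volumes of an active/inactive duplicated cross-peak pair."""

    v_active: float
    v_inactive: float
    residue: str = ""
    condition: dict = field(default_factory=dict)
    v_active_err: float = 0.0
    v_inactive_err: float = 0.0

    def __post_init__(self) -> None:
        if self.v_active < 0 or self.v_inactive < 0:
            raise SchemeValidationError("peak volumes must be >= 0")
        if self.v_active + self.v_inactive <= 0:
            raise SchemeValidationError("total peak volume must be > 0")


def population_from_volumes(p: PeakPairVolumes) -> tuple[float, float]:
    """Inactive fraction v_I/(v_A+v_I) with first-order propagated error.

    Assumes equal per-molecule peak intensity for the two conformers (same
    residue, similar relaxation) — the standard slow-exchange reading.
    """
    total = p.v_active + p.v_inactive
    frac = p.v_inactive / total
    # d(frac)/dv_I = v_A/total^2 ; d(frac)/dv_A = -v_I/total^2
    var = (p.v_active * p.v_inactive_err) ** 2 + (p.v_inactive * p.v_active_err) ** 2
    return frac, float(np.sqrt(var)) / total**2


def aggregate_populations(
    pairs: Sequence[PeakPairVolumes], outlier_sd: float = 3.0
) -> tuple[float, float, list[int]]:
    """Error-weighted mean inactive fraction across residues.

    Inverse-variance weighting when errors are available, else plain mean.
    Residues deviating by more than ``outlier_sd`` standard deviations from
    the weighted mean are flagged (indices returned), not removed.
    The aggregate always lies within the convex hull of the inputs.
    """
    fracs, errs = zip(*(population_from_volumes(p) for p in pairs))
    fracs = np.array(fracs)
    errs = np.array(errs)
    if np.all(errs > 0):
        w = 1.0 / errs**2
    else:
        w = np.ones_like(fracs)
    mean = float(np.sum(w * fracs) / np.sum(w))
    err = float(1.0 / np.sqrt(np.sum(w))) if np.all(errs > 0) else float(np.std(fracs) / np.sqrt(len(fracs)))
    spread = float(np.std(fracs)) if len(fracs) > 1 else 0.0
    outliers = (
        [i for i, f in enumerate(fracs) if spread > 0 and abs(f - mean) > outlier_sd * spread]
        if len(fracs) > 2
        else []
    )
    return mean, err, outliers


def integrate_peak(
    spectrum: TimeSeries,
    window: tuple[float, float],
    baseline: float | None = None,
) -> float:
    """Baseline-corrected trapezoidal integral of a 1D trace over ``window``.

    ``spectrum.times`` is the frequency axis (Hz).  If ``baseline`` is None
    it is estimated as the median intensity of the outer 5% of points at
    each edge of the spectrum — for symmetric noise the median there is an
    unbiased floor estimate (peaks are assumed away from the edges).
    """
    lo, hi = sorted(window)
    x, y = spectrum.times, spectrum.values
    if lo < x[0] or hi > x[-1]:
        raise SchemeValidationError("integration window outside the spectrum")
    if baseline is None:
        n_edge = max(int(0.05 * len(y)), 2)
        baseline = float(np.median(np.concatenate([y[:n_edge], y[-n_edge:]])))
    mask = (x >= lo) & (x <= hi)
    if np.sum(mask) < 2:
        return 0.0
    return float(np.trapezoid(y[mask] - baseline, x[mask]))


@dataclass
class RelaxationSeries:
    """Signal relaxing toward equilibrium after a perturbation (pH jump)."""

    times: np.ndarray
    signal: np.ndarray
    condition: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if len(self.times) < 6:
            raise SchemeValidationError("need >= 6 points in a relaxation series")
        if not np.all(np.diff(self.times) > 0):
            raise SchemeValidationError("times must be strictly increasing")

    @classmethod
    def from_timeseries(cls, ts: TimeSeries) -> "RelaxationSeries":
        return cls(times=ts.times, signal=ts.values, condition=dict(ts.meta))


def fit_relaxation(series: RelaxationSeries, seed: int = 0) -> FitResult:
    """Single-exponential fit S(t) = S_inf + (S_0 - S_inf) exp(-k_obs t).

    k_obs is fitted in log space; endpoint and amplitude are linear (variable
    projection).  Raises :class:`NoRelaxationError` when the 2-sigma CI of
    k_obs includes zero or the amplitude is indistinguishable from the
    residual scatter.  A Wald-Wolfowitz runs test on the residual signs is
    reported in ``extra['runs_z']``.
    """
    t = series.times - series.times[0]
    y = series.signal
    span = max(t[-1], 1e-12)

    def residual(x_log):
        k = float(np.exp(x_log[0]))
        X = np.column_stack([np.ones_like(t), np.exp(-k * t)])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        return X @ coef - y

    best = None
    for k0 in np.geomspace(0.3 / span, 30.0 / span, 7):
        r = least_squares(residual, [np.log(k0)], bounds=([np.log(1e-12)], [np.log(1e12)]))
        if best is None or r.cost < best.cost:
            best = r
    k_obs = float(np.exp(best.x[0]))
    X = np.column_stack([np.ones_like(t), np.exp(-k_obs * t)])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    s_inf, amp = float(coef[0]), float(coef[1])
    resid = X @ coef - y
    sd_k = float(stderr_linear_from_log(best, [k_obs], len(y))[0])

    noise = float(np.std(resid))
    amp_floor = max(3.0 * noise / np.sqrt(len(y)), 1e-12 * max(float(np.max(np.abs(y))), 1.0))
    if abs(amp) <= amp_floor or (np.isfinite(sd_k) and k_obs - 2 * sd_k <= 0):
        raise NoRelaxationError(
            f"no relaxation detected (amplitude {amp:.3g} vs noise {noise:.3g}, "
            f"k_obs {k_obs:.3g} ± {sd_k:.3g})"
        )
    # runs test on residual signs: z ~ N(0,1) under random scatter
    signs = np.sign(resid[np.abs(resid) > 0])
    runs_z = np.nan
    if len(signs) > 3:
        n_pos = int(np.sum(signs > 0))
        n_neg = len(signs) - n_pos
        if n_pos and n_neg:
            runs = 1 + int(np.sum(signs[1:] != signs[:-1]))
            mu = 2 * n_pos * n_neg / (n_pos + n_neg) + 1
            var = (mu - 1) * (mu - 2) / (n_pos + n_neg - 1)
            runs_z = (runs - mu) / np.sqrt(var) if var > 0 else np.nan

    return FitResult(
        params={"k_obs": k_obs, "endpoint": s_inf, "amplitude": amp},
        stderr={"k_obs": sd_k, "endpoint": np.nan, "amplitude": np.nan},
        cost=float(best.cost),
        residuals=resid,
        n_obs=len(y),
        n_free=3,
        converged=bool(best.success),
        seed=seed,
        extra={"runs_z": float(runs_z)},
    )


def activation_rate(k_obs: float, p_active: float) -> tuple[float, float]:
    """Split k_obs into (k_ina->act, k_act->ina) using the active fraction.

    Two-state identity: the two rates sum to k_obs exactly;
    k_ina->act = p_active * k_obs.
    """
    if not 0 < p_active < 1:
        raise SchemeValidationError("p_active must be strictly inside (0, 1)")
    if k_obs <= 0:
        raise SchemeValidationError("k_obs must be > 0")
    k_ia = p_active * k_obs
    return k_ia, k_obs - k_ia


@dataclass(frozen=True)
class VantHoffResult:
    """Two-point (or regression) van't Hoff estimate for A <-> I.

    K(T) = p_I/(1-p_I); ln K = -dH/(R T) + dS/R.  Intended only for
    interpolating populations between the measured temperatures.
    """

    dH: float  # J/mol
    dS: float  # J/(mol K)

    def equilibrium_constant(self, T: float) -> float:
        return float(np.exp(-self.dH / (R_GAS * T) + self.dS / R_GAS))

    def population_inactive(self, T: float) -> float:
        K = self.equilibrium_constant(T)
        return K / (1.0 + K)


def vant_hoff_shift(populations: Sequence[tuple[float, float]]) -> VantHoffResult:
    """Fit ln K vs 1/T for the inactive<->active equilibrium.

    ``populations`` is a list of (temperature K, inactive fraction) pairs,
    fractions strictly inside (0, 1).  Two points give the exact two-point
    formula; more give an OLS regression.
    """
    if len(populations) < 2:
        raise SchemeValidationError("need populations at >= 2 temperatures")
    T = np.array([p[0] for p in populations], dtype=float)
    pI = np.array([p[1] for p in populations], dtype=float)
    if np.any((pI <= 0) | (pI >= 1)):
        raise SchemeValidationError("populations must be strictly inside (0, 1)")
    lnK = np.log(pI / (1.0 - pI))
    X = np.column_stack([np.ones_like(T), 1.0 / T])
    beta, *_ = np.linalg.lstsq(X, lnK, rcond=None)
    intercept, slope = beta
    return VantHoffResult(dH=float(-slope * R_GAS), dS=float(intercept * R_GAS))
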