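"""Seeded generators for the three experimental data streams.

Everything downstream is testable by parameter recovery: each generator
simulates its observable from known ("truth") parameters, adds additive
Gaussian noise from a seeded RNG, and returns a dataset that stores the
truth separately from the traces.  Named presets ship the study variants:

========  ======  =========  =========  ==============================
preset      K2     p_I 25C     p_I 40C   binding scheme
========  ======  =========  =========  ==============================
HG3       276 uM    25%        (n/a)     conformational selection
HG3.7     16.5 uM   25%        58%       conformational selection
HG3.17    4.4 uM     5%        42%       CS + induced fit
========  ======  =========  =========  ==============================

Interconversion rates sit in the observed 1e-4..1e-3 s^-1 band.  Constants
the source text does not print (k_on, induced-fit rates, progress-curve
parameters, fluorescence coefficients) have physically plausible defaults
and are listed as assumed in each preset's provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .binding_kinetics import BindingParams, simulate_binding
from .progress_curves import MMExtendedParams, simulate_progress
from .scheme_core import SchemeValidationError, TimeSeries

__all__ = [
    "NoiseModel",
    "SyntheticDataset",
    "VariantPreset",
    "PRESETS",
    "gen_stopped_flow",
    "gen_progress_curves",
    "gen_nmr_peaks",
    "gen_ph_jump",
    "stopped_flow_from_preset",
    "ph_jump_from_preset",
    "nmr_peaks_from_preset",
]

GENERATOR_VERSION = "1.0"
DEFAULT_DEAD_TIME = 1.5e-3  # s, instrument mixing dead time (assumed)


@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian noise; identical seed implies identical dataset."""

    sigma: float = 0.0
    seed: int = 0
    kind: str = "additive-gaussian"

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise SchemeValidationError("noise sigma must be >= 0")
        if self.kind != "additive-gaussian":
            raise SchemeValidationError(f"unsupported noise kind {self.kind!r}")


@dataclass
class SyntheticDataset:
    """Traces plus the generating truth (kept separate) and provenance."""

    traces: list[TimeSeries]
    truth: dict
    provenance: dict = field(default_factory=dict)

    def trace_by(self, **meta) -> TimeSeries:
        for tr in self.traces:
            if all(tr.meta.get(k) == v for k, v in meta.items()):
                return tr
        raise KeyError(f"no trace with meta {meta}")


@dataclass(frozen=True)
class VariantPreset:
    """Generating parameters for one enzyme variant."""

    name: str
    binding: BindingParams
    mm: MMExtendedParams
    p_inactive_25C: float
    p_inactive_40C: float | None
    fluor_coeffs: dict
    ligand_concs: tuple  # M
    E0_binding: float  # M
    nmr_centers_ppm: tuple = (8.90, 8.00)
    nmr_widths_hz: tuple = (18.0, 18.0)
    assumed: tuple = ()

    @property
    def scheme(self) -> str:
        return "CS+IF" if self.binding.has_induced_fit else "CS"

    def p_inactive(self, temperature_C: float) -> float:
        if abs(temperature_C - 25.0) < 1e-9:
            return self.p_inactive_25C
        if abs(temperature_C - 40.0) < 1e-9:
            if self.p_inactive_40C is None:
                raise SchemeValidationError(f"no 40 C population for preset {self.name}")
            return self.p_inactive_40C
        raise SchemeValidationError("presets store populations at 25 C and 40 C only")


def _preset(name, k_obs, p_i25, p_i40, k2, k_on, kif, mm_kwargs, lig_factors):
    k_ia = (1.0 - p_i25) * k_obs
    k_ai = p_i25 * k_obs
    binding = BindingParams(
        k_ia=k_ia, k_ai=k_ai, k_on=k_on, k_off=k2 * k_on,
        k_if=kif[0] if kif else None, k_ir=kif[1] if kif else None,
    )
    mm = MMExtendedParams(k_ia=k_ia, k_ai=k_ai, **mm_kwargs)
    assumed = ["k_on", "dead_time", "fluor_coeffs", "progress_curve_params"]
    if kif:
        assumed.append("k_if/k_ir")
    return VariantPreset(
        name=name,
        binding=binding,
        mm=mm,
        p_inactive_25C=p_i25,
        p_inactive_40C=p_i40,
        fluor_coeffs={"I": 2.0e7, "A": 2.0e7, "AL": 1.1e7, "ALs": 8.0e6},
        ligand_concs=tuple(k2 * f for f in lig_factors),
        E0_binding=5e-8,
        assumed=tuple(assumed),
    )


_LIG_FACTORS = (0.25, 0.5, 1.0, 2.0, 4.0, 8.0)

PRESETS: dict[str, VariantPreset] = {
    "HG3": _preset(
        "HG3", k_obs=4e-4, p_i25=0.25, p_i40=None, k2=276e-6, k_on=1e5, kif=None,
        mm_kwargs=dict(k1=1e7, k_minus1=1.2e4, k_cat=0.7, kp_on=1e7, kp_off=2.0e3,
                       eps_path=1.5e4),
        lig_factors=_LIG_FACTORS,
    ),
    "HG3.7": _preset(
        "HG3.7", k_obs=2e-4, p_i25=0.25, p_i40=0.58, k2=16.5e-6, k_on=1e5, kif=None,
        mm_kwargs=dict(k1=1e7, k_minus1=8.0e3, k_cat=50.0, kp_on=1e7, kp_off=8.0e3,
                       eps_path=1.5e4),
        lig_factors=_LIG_FACTORS,
    ),
    "HG3.17": _preset(
        "HG3.17", k_obs=9e-4, p_i25=0.05, p_i40=0.42, k2=4.4e-6, k_on=1e6,
        kif=(0.5, 1.5),
        mm_kwargs=dict(k1=1e7, k_minus1=2.0e3, k_cat=700.0, kp_on=1e7, kp_off=3.0e4,
                       eps_path=1.5e4),
        lig_factors=_LIG_FACTORS,
    ),
}


def _provenance(generator: str, noise: NoiseModel, **extra) -> dict:
    return {
        "generator": generator,
        "version": GENERATOR_VERSION,
        "seed": noise.seed,
        "noise_sigma": noise.sigma,
        "noise_kind": noise.kind,
        **extra,
    }


# ---------------------------------------------------------------------------
# stopped-flow binding traces
# ---------------------------------------------------------------------------

def gen_stopped_flow(
    params: BindingParams,
    ligand_concs: Sequence[float],
    E0: float,
    t_end: float,
    n_points: int = 300,
    fluor_coeffs: dict | None = None,
    noise: NoiseModel = NoiseModel(),
    dead_time: float = DEFAULT_DEAD_TIME,
    pseudo_first_order: bool = True,
) -> SyntheticDataset:
    """Fluorescence traces at a ladder of ligand concentrations.

    The time grid is log-spaced from the instrument dead time (front of each
    trace truncated) to ``t_end``, capturing both the fast binding phase and
    the slow conformational phase.  The observable is linear in the state
    populations with per-species coefficients ``fluor_coeffs``.
    """
    if E0 <= 0 or any(L <= 0 for L in ligand_concs):
        raise SchemeValidationError("concentrations must be > 0")
    if pseudo_first_order and any(L < 10 * E0 for L in ligand_concs):
        raise SchemeValidationError(
            "pseudo-first-order requires every ligand conc >= 10 * E0"
        )
    coeffs = dict(fluor_coeffs or {"I": 1.0, "A": 1.0, "AL": 0.5, "ALs": 0.4})
    times = np.geomspace(dead_time, t_end, n_points)
    rng = np.random.default_rng(noise.seed)
    traces = []
    for i, L in enumerate(ligand_concs):
        traj = simulate_binding(params, float(L), E0, times)
        signal = np.zeros_like(times)
        for sp, c in coeffs.items():
            if sp in traj:
                signal = signal + c * traj[sp].values
        values = signal + rng.normal(0.0, noise.sigma, size=signal.shape)
        traces.append(
            TimeSeries(
                times=times,
                values=values,
                sigma=np.full_like(times, noise.sigma) if noise.sigma > 0 else None,
                meta={
                    "kind": "stopped-flow",
                    "trace": i,
                    "ligand_M": float(L),
                    "enzyme_M": float(E0),
                },
            )
        )
    truth = {"binding_params": params.as_dict(), "fluor_coeffs": coeffs, "K2": params.K2}
    return SyntheticDataset(
        traces=traces,
        truth=truth,
        provenance=_provenance(
            "gen_stopped_flow", noise, dead_time=dead_time, t_end=t_end, E0=float(E0)
        ),
    )


# ---------------------------------------------------------------------------
# progress curves
# ---------------------------------------------------------------------------

def gen_progress_curves(
    params: MMExtendedParams,
    S0_list: Sequence[float],
    E0: float,
    t_end: float,
    n_points: int = 200,
    eps_path: float | None = None,
    noise: NoiseModel = NoiseModel(),
    solubility_ceiling: float = 1e-3,
) -> SyntheticDataset:
    """Absorbance progress curves of substrate conversion to completion."""
    if E0 <= 0 or any(s <= 0 for s in S0_list):
        raise SchemeValidationError("concentrations must be > 0")
    if any(s > solubility_ceiling for s in S0_list):
        raise SchemeValidationError(
            f"S0 exceeds the solubility ceiling {solubility_ceiling:g} M"
        )
    if eps_path is not None:
        params = MMExtendedParams(**{**params.as_dict(), "eps_path": eps_path})
    times = np.linspace(0.0, t_end, n_points)
    rng = np.random.default_rng(noise.seed)
    traces, warnings = [], []
    for i, S0 in enumerate(S0_list):
        sim = simulate_progress(params, float(S0), E0, times)
        conversion = (sim.values[-1] - params.baseline) / (params.eps_path * S0)
        if conversion < 0.99:
            warnings.append(
                f"curve {i} (S0={S0:g} M) reaches only {conversion:.1%} conversion at t_end"
            )
        values = sim.values + rng.normal(0.0, noise.sigma, size=times.shape)
        traces.append(
            TimeSeries(
                times=times,
                values=values,
                sigma=np.full_like(times, noise.sigma) if noise.sigma > 0 else None,
                meta={
                    "kind": "progress",
                    "trace": i,
                    "S0_M": float(S0),
                    "E0_M": float(E0),
                    "eps_path": params.eps_path,
                },
            )
        )
    truth = {"mm_params": params.as_dict(), "k_cat": params.k_cat, "K_M": params.K_M,
             "K_S": params.K_S, "K_P": params.K_P}
    return SyntheticDataset(
        traces=traces,
        truth=truth,
        provenance=_provenance(
            "gen_progress_curves", noise, t_end=t_end, E0=float(E0), warnings=warnings
        ),
    )


# ---------------------------------------------------------------------------
# NMR observables
# ---------------------------------------------------------------------------

def _lorentzian(f: np.ndarray, center: float, fwhm: float, area: float) -> np.ndarray:
    hwhm = fwhm / 2.0
    return area / np.pi * hwhm / ((f - center) ** 2 + hwhm**2)


def gen_nmr_peaks(
    p_inactive: float,
    centers: tuple[float, float] = (8.90, 8.00),
    widths: tuple[float, float] = (18.0, 18.0),
    total_area: float = 1.0,
    noise: NoiseModel = NoiseModel(),
    spectrometer_mhz: float = 600.0,
    n_points: int = 4096,
    margin_widths: float = 25.0,
) -> SyntheticDataset:
    """Two-Lorentzian 1D spectrum of a duplicated peak in slow exchange.

    ``centers`` are ppm (active first, inactive second), ``widths`` are FWHM
    in Hz; areas split (1-p)/p of ``total_area``.  The frequency axis of the
    returned trace is Hz.  Slow exchange demands a separation of at least 3
    linewidths.
    """
    if not 0 <= p_inactive <= 1:
        raise SchemeValidationError("p_inactive must be in [0, 1]")
    f_active, f_inactive = (c * spectrometer_mhz for c in centers)
    wmax = max(widths)
    if abs(f_active - f_inactive) < 3.0 * wmax:
        raise SchemeValidationError(
            "peaks must be separated by >= 3 linewidths (slow exchange)"
        )
    lo = min(f_active, f_inactive) - margin_widths * wmax
    hi = max(f_active, f_inactive) + margin_widths * wmax
    f = np.linspace(lo, hi, n_points)
    spec = _lorentzian(f, f_active, widths[0], (1.0 - p_inactive) * total_area)
    spec = spec + _lorentzian(f, f_inactive, widths[1], p_inactive * total_area)
    rng = np.random.default_rng(noise.seed)
    values = spec + rng.normal(0.0, noise.sigma, size=f.shape)
    trace = TimeSeries(
        times=f,
        values=values,
        meta={
            "kind": "nmr-spectrum",
            "axis": "Hz",
            "center_active_hz": f_active,
            "center_inactive_hz": f_inactive,
            "width_active_hz": widths[0],
            "width_inactive_hz": widths[1],
        },
    )
    truth = {"p_inactive": p_inactive, "total_area": total_area}
    return SyntheticDataset(
        traces=[trace],
        truth=truth,
        provenance=_provenance("gen_nmr_peaks", noise, spectrometer_mhz=spectrometer_mhz),
    )


def gen_ph_jump(
    k_ia: float,
    k_ai: float,
    p_start: float,
    t_end: float,
    n_points: int = 50,
    observable: str = "peak-area",
    noise: NoiseModel = NoiseModel(),
) -> SyntheticDataset:
    """Relaxation of the active population after a pH jump.

    p_active(t) decays exponentially from ``p_start`` to the equilibrium
    value k_ia/(k_ia+k_ai) with rate k_obs = k_ia + k_ai.  ``observable``
    selects the readout: peak-area and activity are proportional to
    p_active; fluorescence is an affine map of it.
    """
    if k_ia <= 0 or k_ai <= 0:
        raise SchemeValidationError("rates must be > 0")
    if not 0 <= p_start <= 1:
        raise SchemeValidationError("p_start must be in [0, 1]")
    k_obs = k_ia + k_ai
    if t_end < 3.0 / k_obs:
        raise SchemeValidationError("t_end must cover >= 3 relaxation times")
    if observable not in ("peak-area", "activity", "fluorescence"):
        raise SchemeValidationError(f"unknown observable {observable!r}")
    t = np.linspace(0.0, t_end, n_points)
    p_eq = k_ia / k_obs
    p_active = p_eq + (p_start - p_eq) * np.exp(-k_obs * t)
    signal = 0.2 + 0.8 * p_active if observable == "fluorescence" else p_active
    rng = np.random.default_rng(noise.seed)
    values = signal + rng.normal(0.0, noise.sigma, size=t.shape)
    trace = TimeSeries(
        times=t,
        values=values,
        sigma=np.full_like(t, noise.sigma) if noise.sigma > 0 else None,
        meta={"kind": "relaxation", "observable": observable, "p_start": p_start},
    )
    truth = {"k_ia": k_ia, "k_ai": k_ai, "k_obs": k_obs, "p_active_eq": p_eq}
    return SyntheticDataset(
        traces=[trace],
        truth=truth,
        provenance=_provenance("gen_ph_jump", noise, t_end=t_end, observable=observable),
    )


# ---------------------------------------------------------------------------
# preset-driven convenience generators
# ---------------------------------------------------------------------------

def stopped_flow_from_preset(
    preset: str | VariantPreset,
    seed: int = 0,
    rel_noise: float = 0.01,
    n_points: int = 300,
) -> SyntheticDataset:
    """Preset stopped-flow ladder with noise sigma = rel_noise * signal range."""
    p = PRESETS[preset] if isinstance(preset, str) else preset
    slow = p.binding.k_ia + p.binding.k_ai
    t_end = 6.0 / slow
    quiet = gen_stopped_flow(
        p.binding, p.ligand_concs, p.E0_binding, t_end, n_points,
        p.fluor_coeffs, NoiseModel(sigma=0.0, seed=seed),
    )
    rng_range = np.ptp(np.concatenate([tr.values for tr in quiet.traces]))
    ds = gen_stopped_flow(
        p.binding, p.ligand_concs, p.E0_binding, t_end, n_points,
        p.fluor_coeffs, NoiseModel(sigma=rel_noise * rng_range, seed=seed),
    )
    ds.provenance["preset"] = p.name
    ds.provenance["assumed"] = list(p.assumed)
    ds.truth["scheme"] = p.scheme
    return ds


def ph_jump_from_preset(
    preset: str | VariantPreset,
    seed: int = 0,
    rel_noise: float = 0.02,
    p_start: float | None = None,
    n_points: int = 60,
) -> SyntheticDataset:
    """Preset pH-jump relaxation (start from a high-pH inactive-rich state)."""
    p = PRESETS[preset] if isinstance(preset, str) else preset
    b = p.binding
    start = 0.25 if p_start is None else p_start
    ds = gen_ph_jump(
        b.k_ia, b.k_ai, start, t_end=6.0 / (b.k_ia + b.k_ai), n_points=n_points,
        observable="peak-area", noise=NoiseModel(sigma=rel_noise, seed=seed),
    )
    ds.provenance["preset"] = p.name
    return ds


def nmr_peaks_from_preset(
    preset: str | VariantPreset,
    temperature_C: float = 25.0,
    seed: int = 0,
    rel_noise: float = 0.005,
) -> SyntheticDataset:
    """Preset duplicated-peak spectrum; noise scaled to the major peak height."""
    p = PRESETS[preset] if isinstance(preset, str) else preset
    p_i = p.p_inactive(temperature_C)
    height = 2.0 / (np.pi * min(p.nmr_widths_hz))  # unit-area Lorentzian height
    ds = gen_nmr_peaks(
        p_i, centers=p.nmr_centers_ppm, widths=p.nmr_widths_hz, total_area=1.0,
        noise=NoiseModel(sigma=rel_noise * height, seed=seed),
    )
    ds.provenance["preset"] = p.name
    ds.provenance["temperature_C"] = temperature_C
    return ds
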