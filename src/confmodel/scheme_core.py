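"""Declarative mass-action kinetic schemes and their numerics.

A :class:`KineticScheme` is a list of uni/bimolecular reactions over named
species with named rate constants and linear observables.  From it we build a
mass-action right-hand side, integrate stiff trajectories with
:func:`scipy.integrate.solve_ivp`, extract conservation laws from the
stoichiometry, and solve for chemical equilibrium by damped Newton iteration
on log-concentrations (with an integrate-to-steady-state fallback).

Units are fixed internally: seconds, molar.  Unimolecular rate constants are
s^-1, bimolecular ones M^-1 s^-1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import null_space

__all__ = [
    "SchemeValidationError",
    "IntegrationError",
    "EquilibriumError",
    "Reaction",
    "Observable",
    "KineticScheme",
    "ConcentrationState",
    "TimeSeries",
    "build_rhs",
    "integrate",
    "equilibrium",
]

DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-12  # molar


class SchemeValidationError(ValueError):
    """A scheme or state violates its declared invariants."""


class IntegrationError(RuntimeError):
    """The ODE integrator failed; carries scheme name and failure time."""

    def __init__(self, scheme_name: str, t_fail: float, message: str):
        self.scheme_name = scheme_name
        self.t_fail = t_fail
        super().__init__(
            f"integration of scheme {scheme_name!r} failed at t={t_fail:.6g} s: {message}"
        )


class EquilibriumError(RuntimeError):
    """Newton equilibrium solve failed to converge.

    Callers may fall back to ``integrate`` to a long horizon; the error
    message says so.
    """


@dataclass(frozen=True)
class Reaction:
    """One elementary step: reactant multiset -> product multiset at ``rate``.

    Each side holds at most two molecules (uni/bimolecular only); species may
    repeat, e.g. ``("A", "A")`` for dimerisation.
    """

    reactants: tuple[str, ...]
    products: tuple[str, ...]
    rate: str

    def __post_init__(self) -> None:
        if len(self.reactants) > 2 or len(self.products) > 2:
            raise SchemeValidationError(
                f"reaction {self._label()} exceeds bimolecular order"
            )
        if len(self.reactants) == 0:
            raise SchemeValidationError(
                f"reaction {self._label()} has no reactants (zeroth-order steps unsupported)"
            )

    def _label(self) -> str:
        lhs = " + ".join(self.reactants) if self.reactants else "0"
        rhs = " + ".join(self.products) if self.products else "0"
        return f"'{lhs} -> {rhs} : {self.rate}'"


@dataclass(frozen=True)
class Observable:
    """Linear readout: sum_i coeff[i]*[species_i] + baseline."""

    coeffs: Mapping[str, float]
    baseline: float = 0.0


@dataclass
class KineticScheme:
    species: list[str]
    reactions: list[Reaction]
    rate_constants: dict[str, float]
    observables: dict[str, Observable] = field(default_factory=dict)
    name: str = "scheme"

    def __post_init__(self) -> None:
        self.validate()

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        if len(set(self.species)) != len(self.species):
            raise SchemeValidationError(f"duplicate species names in {self.name!r}")
        declared = set(self.species)
        for rxn in self.reactions:
            for sp in (*rxn.reactants, *rxn.products):
                if sp not in declared:
                    raise SchemeValidationError(
                        f"reaction {rxn._label()} references undeclared species {sp!r}"
                    )
            if rxn.rate not in self.rate_constants:
                raise SchemeValidationError(
                    f"reaction {rxn._label()} references undeclared rate constant {rxn.rate!r}"
                )
        for kname, kval in self.rate_constants.items():
            if not np.isfinite(kval) or kval < 0:
                raise SchemeValidationError(
                    f"rate constant {kname!r} = {kval} must be finite and >= 0"
                )
        for oname, obs in self.observables.items():
            for sp in obs.coeffs:
                if sp not in declared:
                    raise SchemeValidationError(
                        f"observable {oname!r} references undeclared species {sp!r}"
                    )

    # -- structure --------------------------------------------------------
    @property
    def n_species(self) -> int:
        return len(self.species)

    def species_index(self, name: str) -> int:
        return self.species.index(name)

    def stoichiometry(self) -> np.ndarray:
        """Net stoichiometry matrix N (n_species x n_reactions)."""
        N = np.zeros((len(self.species), len(self.reactions)))
        idx = {sp: i for i, sp in enumerate(self.species)}
        for j, rxn in enumerate(self.reactions):
            for sp in rxn.reactants:
                N[idx[sp], j] -= 1.0
            for sp in rxn.products:
                N[idx[sp], j] += 1.0
        return N

    def conservation_laws(self) -> np.ndarray:
        """Rows c with c @ dy/dt = 0 along every trajectory.

        Left null space of the stoichiometry matrix; rows are orthonormal
        (SVD basis), so they are linear combinations of the intuitive
        moiety totals rather than the totals themselves.
        """
        N = self.stoichiometry()
        if N.shape[1] == 0:
            return np.eye(len(self.species))
        ns = null_space(N.T)
        return ns.T  # (n_laws, n_species)

    def rate_vector(self) -> np.ndarray:
        return np.array([self.rate_constants[r.rate] for r in self.reactions])

    def with_rates(self, updates: Mapping[str, float]) -> "KineticScheme":
        """Copy of the scheme with some rate constants replaced."""
        unknown = set(updates) - set(self.rate_constants)
        if unknown:
            raise SchemeValidationError(f"unknown rate constants {sorted(unknown)}")
        rates = dict(self.rate_constants)
        rates.update(updates)
        return KineticScheme(
            species=list(self.species),
            reactions=list(self.reactions),
            rate_constants=rates,
            observables=dict(self.observables),
            name=self.name,
        )

    def observe(self, name: str, concentrations: np.ndarray) -> np.ndarray:
        """Evaluate a named observable on a (n_times, n_species) array."""
        obs = self.observables[name]
        conc = np.atleast_2d(concentrations)
        out = np.full(conc.shape[0], float(obs.baseline))
        for sp, c in obs.coeffs.items():
            out = out + c * conc[:, self.species_index(sp)]
        return out


@dataclass
class ConcentrationState:
    """Molar concentrations aligned with ``scheme.species``."""

    concentrations: np.ndarray

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.concentrations.ndim != 1:
            raise SchemeValidationError("concentrations must be a 1-D vector")
        if np.any(self.concentrations < -DEFAULT_ATOL):
            raise SchemeValidationError(
                f"negative concentration below tolerance: min={self.concentrations.min():.3g}"
            )
        self.concentrations = np.clip(self.concentrations, 0.0, None)


@dataclass
class TimeSeries:
    """One observable channel on a strictly increasing time grid (seconds)."""

    times: np.ndarray
    values: np.ndarray
    sigma: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise SchemeValidationError("times and values must be matching 1-D arrays")
        if len(self.times) >= 2 and not np.all(np.diff(self.times) > 0):
            bad = int(np.argmax(np.diff(self.times) <= 0)) + 1
            raise SchemeValidationError(
                f"times must be strictly increasing (violated at index {bad})"
            )
        if not np.all(np.isfinite(self.values)):
            raise SchemeValidationError("values must be finite")
        if self.sigma is not None:
            self.sigma = np.broadcast_to(
                np.asarray(self.sigma, dtype=float), self.times.shape
            ).copy()
            if np.any(self.sigma <= 0):
                raise SchemeValidationError("sigma must be > 0 when present")

    def __len__(self) -> int:
        return len(self.times)


# ---------------------------------------------------------------------------
# mass-action right-hand side
# ---------------------------------------------------------------------------

def build_rhs(scheme: KineticScheme) -> Callable[[float, np.ndarray], np.ndarray]:
    """Compile the scheme's mass-action derivative function ``f(t, y)``.

    Also attaches ``f.jac(t, y)`` returning the analytic Jacobian, which the
    stiff integrators use.
    """
    scheme.validate()
    N = scheme.stoichiometry()
    k = scheme.rate_vector()
    idx = {sp: i for i, sp in enumerate(scheme.species)}
    reactant_idx = [tuple(idx[sp] for sp in r.reactants) for r in scheme.reactions]

    def flux(y: np.ndarray) -> np.ndarray:
        v = k.copy()
        for j, rs in enumerate(reactant_idx):
            for i in rs:
                v[j] *= y[i]
        return v

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        return N @ flux(y)

    def jac(t: float, y: np.ndarray) -> np.ndarray:
        dv = np.zeros((len(k), len(y)))
        for j, rs in enumerate(reactant_idx):
            if len(rs) == 1:
                dv[j, rs[0]] = k[j]
            else:  # bimolecular, possibly A+A
                a, b = rs
                dv[j, a] += k[j] * y[b]
                dv[j, b] += k[j] * y[a]
        return N @ dv

    rhs.flux = flux  # type: ignore[attr-defined]
    rhs.jac = jac  # type: ignore[attr-defined]
    return rhs


def integrate(
    scheme: KineticScheme,
    init: ConcentrationState | Sequence[float],
    times: Sequence[float],
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    method: str = "LSODA",
) -> dict[str, TimeSeries]:
    """Integrate the scheme and return one TimeSeries per species.

    Stiff-capable by default; rate constants may span many orders of
    magnitude.  Small negative excursions (>-atol*100) are clipped to zero;
    anything worse raises.
    """
    if not isinstance(init, ConcentrationState):
        init = ConcentrationState(np.asarray(init, dtype=float))
    y0 = init.concentrations
    if len(y0) != scheme.n_species:
        raise SchemeValidationError(
            f"initial state has {len(y0)} entries, scheme has {scheme.n_species} species"
        )
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or len(t) < 2 or not np.all(np.diff(t) > 0):
        raise SchemeValidationError("time grid must be 1-D, strictly increasing")
    if t[0] < 0:
        raise SchemeValidationError("time grid must start at t >= 0")

    rhs = build_rhs(scheme)
    t0 = 0.0 if t[0] > 0 else t[0]
    sol = solve_ivp(
        rhs,
        (t0, t[-1]),
        y0,
        t_eval=t,
        rtol=rtol,
        atol=atol,
        method=method,
        jac=rhs.jac,
    )
    if not sol.success:
        if method != "BDF":  # LSODA occasionally stalls on extreme stiffness
            return integrate(scheme, init, times, rtol, atol, method="BDF")
        raise IntegrationError(scheme.name, float(sol.t[-1]) if len(sol.t) else t0, sol.message)

    y = sol.y  # (n_species, n_times)
    floor = -100 * atol
    if np.any(y < floor):
        raise IntegrationError(
            scheme.name,
            float(t[int(np.argmax((y < floor).any(axis=0)))]),
            f"negative concentration {y.min():.3g} below tolerance",
        )
    y = np.clip(y, 0.0, None)
    return {
        sp: TimeSeries(times=t, values=y[i], meta={"species": sp, "scheme": scheme.name})
        for i, sp in enumerate(scheme.species)
    }


def trajectory_matrix(traj: Mapping[str, TimeSeries], scheme: KineticScheme) -> np.ndarray:
    """Stack a per-species trajectory dict into (n_times, n_species)."""
    return np.column_stack([traj[sp].values for sp in scheme.species])


# ---------------------------------------------------------------------------
# equilibrium
# ---------------------------------------------------------------------------

def equilibrium(
    scheme: KineticScheme,
    init: ConcentrationState | Sequence[float],
    tol: float = 1e-10,
    max_iter: int = 200,
) -> ConcentrationState:
    """Equilibrium state reached from ``init`` (which fixes the conserved totals).

    Damped Newton on log-concentrations (positivity-preserving); if Newton
    stalls, falls back to integrating to t = 1000/min(rate) and polishing.
    Net reaction fluxes at the returned state are below ``tol`` times the
    characteristic flux scale.
    """
    if not isinstance(init, ConcentrationState):
        init = ConcentrationState(np.asarray(init, dtype=float))
    y0 = init.concentrations
    rhs = build_rhs(scheme)
    N = scheme.stoichiometry()
    absN = np.abs(N)
    C = scheme.conservation_laws()
    totals = C @ y0
    t_norm = np.maximum(np.abs(totals), DEFAULT_ATOL)
    scale = max(float(np.max(np.abs(y0))), DEFAULT_ATOL)

    def residual(y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Net species flux relative to gross turnover, plus conservation rows.

        Per-species normalisation keeps the criterion meaningful when
        concentrations span many orders of magnitude (nM enzyme, mM ligand).
        Returns (residual, row_scale) so the Jacobian can reuse the scaling.
        """
        v = rhs.flux(y)
        gross = absN @ v  # per-species gross turnover
        d = 1.0 / (gross + max(float(gross.max()), 1e-300) * 1e-13)
        return np.concatenate([d * (N @ v), (C @ y - totals) / t_norm]), d

    def res_jac(y: np.ndarray, d: np.ndarray) -> np.ndarray:
        return np.vstack([d[:, None] * rhs.jac(0.0, y), C / t_norm[:, None]])

    def newton(y: np.ndarray, iters: int) -> tuple[np.ndarray, bool]:
        for _ in range(iters):
            r, d = residual(y)
            if np.max(np.abs(r)) < tol:
                return y, True
            J = res_jac(y, d) * y[np.newaxis, :]  # d r / d log(y)
            du, *_ = np.linalg.lstsq(J, -r, rcond=None)
            du = np.clip(du, -2.0, 2.0)  # trust region in log space
            step, norm0, improved = 1.0, float(np.linalg.norm(r)), False
            while step > 1e-8:
                y_try = y * np.exp(step * du)
                if float(np.linalg.norm(residual(y_try)[0])) < norm0:
                    y, improved = y_try, True
                    break
                step *= 0.5
            if not improved:
                return y, False
        return y, np.max(np.abs(residual(y)[0])) < tol

    y = np.clip(y0, scale * 1e-12, None)  # strictly positive start for log-Newton
    y, converged = newton(y, max_iter)

    if not converged:
        # integration fallback, then polish
        k = scheme.rate_vector()
        kmin = float(k[k > 0].min()) if np.any(k > 0) else 1.0
        t_end = 1000.0 / kmin
        traj = integrate(scheme, init, np.array([0.0, t_end * 0.5, t_end]))
        y = np.clip(
            np.array([traj[sp].values[-1] for sp in scheme.species]), scale * 1e-18, None
        )
        y, converged = newton(y, 50)
        if not converged and np.max(np.abs(residual(y)[0])) > 1e-6:
            raise EquilibriumError(
                f"equilibrium solve for {scheme.name!r} did not converge; "
                "consider integrating to steady state with a longer horizon"
            )
    return ConcentrationState(np.where(y < DEFAULT_ATOL * 1e-3, 0.0, y))


def conservation_drift(traj: Mapping[str, TimeSeries], scheme: KineticScheme) -> float:
    """Max relative drift of any conserved moiety along a trajectory."""
    C = scheme.conservation_laws()
    Y = trajectory_matrix(traj, scheme)
    m = Y @ C.T  # (n_times, n_laws)
    ref = m[0]
    denom = np.where(np.abs(ref) > 0, np.abs(ref), 1.0)
    return float(np.max(np.abs(m - ref) / denom))


def two_state_relaxation_rate(k_fwd: float, k_rev: float) -> float:
    """Closed-form relaxation rate of I<->A: k_obs = k_fwd + k_rev."""
    return k_fwd + k_rev


def binding_quadratic(e_total: float, l_total: float, kd: float) -> float:
    """Closed-form [EL] for E + L <-> EL at equilibrium (quadratic root)."""
    b = e_total + l_total + kd
    disc = b * b - 4.0 * e_total * l_total
    return 0.5 * (b - math.sqrt(max(disc, 0.0)))
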