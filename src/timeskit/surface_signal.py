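"""Electrode adsorption/desorption kinetics and the forward signal map.

The induced charge on the electrode is the convolution of the per-molecule
charge kernel q(t) (the single-molecule impulse response, in Coulomb) with
the net molecular flux J(t):

    Q(t) = A · ∫₀ᵗ q(t − t′) · J(t′) dt′ ,      i(t) = dQ/dt .

J(t) follows Langmuir kinetics on a monolayer of N_s sites:

    N_s · dθ/dt = K₊ · γ · n(0,t) · (1 − θ) − K₋ · θ = J(t) ,

with K₊ an adsorption velocity (m/s), K₋ a desorption flux (1/(m²·s)),
γ the Boltzmann surface partition factor and n(0,t) the near-electrode
concentration.  For constant n the coverage relaxes exponentially with the
dwell time τ_s = N_s / (K₊·γ·n·N_A + K₋), and the flux is exactly
J(t) = K₊·γ·n·N_A · exp(−t/τ_s).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any, Mapping

import numpy as np
from scipy import constants
from scipy.integrate import solve_ivp

from timeskit.model_core import equilibrium_complex

__all__ = [
    "ChargeKernel",
    "SignalTrace",
    "SurfaceKineticsParams",
    "coverage_closed_form",
    "coverage_dynamics",
    "dwell_time",
    "induced_current",
    "langmuir_flux_constant_n",
    "mixture_signal",
    "net_flux",
]


@dataclass(frozen=True)
class SurfaceKineticsParams:
    """Langmuir adsorption/desorption parameters for one species.

    ``k_plus`` has units of velocity (m/s): the adsorption rate constant.
    ``k_minus`` has units of flux (1/(m²·s)): the desorption rate.
    ``site_density`` N_s is the monolayer site density (sites/m²).
    """

    k_plus: float
    k_minus: float
    site_density: float = 3e16
    theta0: float = 0.0

    def __post_init__(self) -> None:
        if self.k_plus < 0 or self.k_minus < 0:
            raise ValueError("k_plus and k_minus must be >= 0")
        if not self.site_density > 0:
            raise ValueError("site_density must be > 0")
        if not 0.0 <= self.theta0 <= 1.0:
            raise ValueError("theta0 must lie in [0, 1]")


@dataclass(frozen=True)
class ChargeKernel:
    """Biphasic per-molecule induced-charge template q(t).

    The time derivative (the current impulse response) is a difference of
    two gamma-shaped pulses: a fast negative dip when the molecular dipole
    aligns on arrival, then a slower positive overshoot as the departing
    molecule drags its counter-ions away:

        q̇(t) = s·[ −a_d·(t/τ_d²)·e^(−t/τ_d) + a_o·(t/τ_o²)·e^(−t/τ_o) ]

    so q(0) = 0 and q(t) → s·(a_o − a_d) (a finite plateau).  ``polarity``
    s = ±1 flips the sign convention.  Amplitudes are in Coulomb, time
    constants in seconds; ``onset_delay`` shifts the response by t_o
    (default 0: onset delays are short next to the timing resolution).
    """

    dip_amplitude: float
    dip_tau: float
    overshoot_amplitude: float
    overshoot_tau: float
    onset_delay: float = 0.0
    polarity: int = 1

    def __post_init__(self) -> None:
        if not (self.dip_tau > 0 and self.overshoot_tau > 0):
            raise ValueError("kernel time constants must be > 0")
        if self.polarity not in (-1, 1):
            raise ValueError("polarity must be ±1")

    def q(self, t: np.ndarray) -> np.ndarray:
        """Induced charge q(t), Coulomb."""
        tt = np.maximum(np.asarray(t, dtype=float) - self.onset_delay, 0.0)
        ed = np.exp(-tt / self.dip_tau)
        eo = np.exp(-tt / self.overshoot_tau)
        qd = -self.dip_amplitude * (1.0 - (1.0 + tt / self.dip_tau) * ed)
        qo = self.overshoot_amplitude * (1.0 - (1.0 + tt / self.overshoot_tau) * eo)
        return self.polarity * (qd + qo)

    def qdot(self, t: np.ndarray) -> np.ndarray:
        """Current impulse response q̇(t), Ampère per molecule."""
        tt = np.asarray(t, dtype=float) - self.onset_delay
        live = tt >= 0.0
        tt = np.maximum(tt, 0.0)
        out = (-self.dip_amplitude * tt / self.dip_tau**2 * np.exp(-tt / self.dip_tau)
               + self.overshoot_amplitude * tt / self.overshoot_tau**2
               * np.exp(-tt / self.overshoot_tau))
        return self.polarity * np.where(live, out, 0.0)


@dataclass
class SignalTrace:
    """Uniformly sampled transient current trace.

    ``t`` in seconds (uniform grid), ``current`` in Ampère; ``meta`` holds
    condition metadata (initial concentrations, flow rate, seed, ...).
    """

    t: np.ndarray
    current: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.current = np.asarray(self.current, dtype=float)
        if self.t.shape != self.current.shape or self.t.ndim != 1:
            raise ValueError("t and current must be 1-D arrays of equal length")
        if len(self.t) < 2:
            raise ValueError("a trace needs at least two samples")
        dt = np.diff(self.t)
        if np.any(~np.isfinite(self.current)) or np.any(~np.isfinite(self.t)):
            raise ValueError("trace contains non-finite values")
        if np.max(np.abs(dt - dt[0])) > 1e-6 * abs(dt[0]):
            raise ValueError("time grid is not uniform")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def sampling_rate(self) -> float:
        return 1.0 / self.dt

    def copy_with(self, current: np.ndarray, **meta: Any) -> "SignalTrace":
        return SignalTrace(t=self.t.copy(), current=np.asarray(current, float),
                           meta={**self.meta, **meta})


def dwell_time(kinetics: SurfaceKineticsParams, gamma: float = 1.0,
               n_o: float = 0.0) -> float:
    """Average surface dwell (adsorption) time τ_s = N_s/(K₊γn₀N_A + K₋).

    This is the relaxation time of the coverage transient; in the
    desorption-dominated (dilute) limit it reduces to N_s/K₋.  ``n_o`` is
    the bulk concentration in mol/m³ (converted to molecules/m³ inside).
    """
    load = kinetics.k_plus * gamma * n_o * constants.N_A
    denom = load + kinetics.k_minus
    if denom <= 0.0:
        raise ValueError("dwell time undefined: K₊γn₀ and K₋ both zero")
    return kinetics.site_density / denom


def coverage_closed_form(kinetics: SurfaceKineticsParams, gamma: float,
                         n_o: float, t: np.ndarray) -> np.ndarray:
    """Closed-form Langmuir coverage for constant near-surface concentration.

    θ(t) = θ_eq + (θ₀ − θ_eq)·exp(−t/τ) with
    θ_eq = K₊γn₀N_A/(K₊γn₀N_A + K₋) and τ = N_s/(K₊γn₀N_A + K₋).
    """
    a = kinetics.k_plus * gamma * n_o * constants.N_A
    b = kinetics.k_minus
    if a + b <= 0.0:
        return np.full_like(np.asarray(t, float), kinetics.theta0)
    theta_eq = a / (a + b)
    tau = kinetics.site_density / (a + b)
    t = np.asarray(t, dtype=float)
    return theta_eq + (kinetics.theta0 - theta_eq) * np.exp(-t / tau)


def coverage_dynamics(kinetics: SurfaceKineticsParams, gamma: float,
                      n_surface: np.ndarray, t_grid: np.ndarray,
                      rtol: float = 1e-10, atol: float = 1e-13) -> np.ndarray:
    """Numerically integrate N_s·dθ/dt = K₊γn(0,t)N_A(1−θ) − K₋θ.

    ``n_surface`` is the near-electrode concentration series (mol/m³) on
    ``t_grid``; linear interpolation between samples.  Returns θ on the
    grid, clipped to [0, 1] only within solver tolerance (values outside
    signal a bug and raise).
    """
    t_grid = np.asarray(t_grid, dtype=float)
    n_surface = np.asarray(n_surface, dtype=float)
    if np.any(n_surface < 0):
        raise ValueError("n_surface must be non-negative")
    a_series = kinetics.k_plus * gamma * constants.N_A * n_surface
    b = kinetics.k_minus
    ns = kinetics.site_density

    def rhs(t: float, th: np.ndarray) -> np.ndarray:
        a = np.interp(t, t_grid, a_series)
        return (a * (1.0 - th[0]) - b * th[0]) / ns

    sol = solve_ivp(rhs, (t_grid[0], t_grid[-1]), [kinetics.theta0],
                    t_eval=t_grid, rtol=rtol, atol=atol, method="LSODA")
    if not sol.success:
        raise RuntimeError(f"coverage ODE failed: {sol.message}")
    theta = sol.y[0]
    if np.any(theta < -1e-6) or np.any(theta > 1.0 + 1e-6):
        raise FloatingPointError("coverage left [0, 1] beyond solver tolerance")
    return np.clip(theta, 0.0, 1.0)


def net_flux(kinetics: SurfaceKineticsParams, gamma: float,
             n_surface: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Net adsorption flux J(t) = K₊γn(0,t)N_A·(1−θ) − K₋θ  [molecules/(m²·s)]."""
    n_surface = np.asarray(n_surface, dtype=float)
    theta = np.asarray(theta, dtype=float)
    return (kinetics.k_plus * gamma * constants.N_A * n_surface * (1.0 - theta)
            - kinetics.k_minus * theta)


def langmuir_flux_constant_n(kinetics: SurfaceKineticsParams, gamma: float,
                             n_o: float, t: np.ndarray) -> np.ndarray:
    """Exact net flux for constant near-surface concentration and θ₀ = 0:
    J(t) = K₊γn₀N_A · exp(−t/τ_s)."""
    a = kinetics.k_plus * gamma * n_o * constants.N_A
    tau = dwell_time(kinetics, gamma, n_o)
    return a * np.exp(-np.asarray(t, dtype=float) / tau)


def _conv_trapz(f: np.ndarray, g: np.ndarray, dt: float) -> np.ndarray:
    """Causal discrete convolution with trapezoidal end-point weights."""
    full = np.convolve(f, g)[: len(f)] * dt
    # trapezoid: half-weight the j = 0 and j = k end points
    full -= 0.5 * dt * (f[0] * g + g[0] * f)
    return full


def induced_current(kernel: ChargeKernel, flux: np.ndarray, t_grid: np.ndarray,
                    area: float, method: str = "impulse") -> SignalTrace:
    """Forward map from molecular flux to induced electrode current.

    ``method="impulse"``: i(t) = A·(q̇ ∗ J)(t) + A·q(0⁺)·J(t) (here q(0)=0).
    ``method="charge"``:  Q(t) = A·(q ∗ J)(t) by trapezoidal convolution,
    then i = dQ/dt by central differences.  The two paths agree to the
    discretisation order and are cross-checked in the test suite.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    flux = np.asarray(flux, dtype=float)
    if t_grid.shape != flux.shape:
        raise ValueError("flux and t_grid must share one uniform grid")
    dt = float(t_grid[1] - t_grid[0])
    tk = t_grid - t_grid[0]
    if method == "impulse":
        current = area * _conv_trapz(kernel.qdot(tk), flux, dt)
    elif method == "charge":
        q_of_t = kernel.q(tk)
        charge = area * _conv_trapz(q_of_t, flux, dt)
        current = np.gradient(charge, dt)
    else:
        raise ValueError(f"unknown method {method!r}")
    return SignalTrace(t=t_grid, current=current, meta={"area_m2": area})


def induced_charge(kernel: ChargeKernel, flux: np.ndarray, t_grid: np.ndarray,
                   area: float) -> np.ndarray:
    """Cumulative induced charge Q(t) = A·(q ∗ J)(t), Coulomb."""
    t_grid = np.asarray(t_grid, dtype=float)
    dt = float(t_grid[1] - t_grid[0])
    return area * _conv_trapz(kernel.q(t_grid - t_grid[0]),
                              np.asarray(flux, float), dt)


def mixture_signal(g_protein: np.ndarray, g_ligand: np.ndarray,
                   g_complex: np.ndarray, x: float, y: float, kd: float,
                   t_grid: np.ndarray, meta: Mapping[str, Any] | None = None
                   ) -> SignalTrace:
    """Superposed current of a protein/ligand mixture at equilibrium.

    i(t) = n_P·G_P(t) + n_L·G_L(t) + n_C·G_C(t) with the equilibrium
    concentrations from the mass-balance quadratic.  Each G is the
    unit-concentration response of its species (A per (mol/m³)), which
    absorbs the unidentifiable product A·γ·q̇.
    """
    eq = equilibrium_complex(x, y, kd)
    current = (eq.n_protein * np.asarray(g_protein, float)
               + eq.n_ligand * np.asarray(g_ligand, float)
               + eq.n_complex * np.asarray(g_complex, float))
    m = dict(meta or {})
    m.update(x=x, y=y, kd=kd,
             n_protein=eq.n_protein, n_ligand=eq.n_ligand, n_complex=eq.n_complex)
    return SignalTrace(t=np.asarray(t_grid, float), current=current, meta=m)
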