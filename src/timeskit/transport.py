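"""One-dimensional diffusion across the half-channel.

Supplies the near-electrode concentration n(0, t) that feeds the surface
adsorption kinetics.  The electrode sits at x = 0; x = L is the channel
centre-line where the concentration is pinned at the bulk value n_o
(Dirichlet).  At x = 0 the diffusive supply balances the net adsorption
flux (Robin condition), optionally coupled to the monolayer-coverage ODE
by operator splitting.

The quasi-steady shortcut :func:`surface_concentration_quasisteady` covers
the regime the analysis pipeline operates in: for times beyond the
diffusion time t_D = L²/(4D) the near-surface concentration is ≈ n_o.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal

import numpy as np
from scipy import constants
from scipy.linalg import solve_banded

DIFFUSION_TIME_CONSTANT = 4.0  # t_D = L² / (constant · D)


def diffusion_time(half_height: float, diffusivity: float,
                   constant: float = DIFFUSION_TIME_CONSTANT) -> float:
    """Characteristic diffusion time t_D = L²/(4·D) across the half-channel."""
    if not (half_height > 0 and diffusivity > 0):
        raise ValueError("half_height and diffusivity must be > 0")
    return half_height * half_height / (constant * diffusivity)


def surface_concentration_quasisteady(
    n_o: float,
    t: np.ndarray | float,
    t_diffusion: float,
    mode: Literal["prefilled", "front"] = "prefilled",
) -> np.ndarray | float:
    """Fast-path near-electrode concentration n(0, t).

    ``prefilled``
        The channel already holds the sample when recording starts
        (the conditioning protocol), so n(0, t) = n_o for all t — the
        quasi-steady regime valid for t ≫ t_D, where depletion by the
        (weak) adsorption flux is negligible.
    ``front``
        The sample front arrives at t = 0: the closed-form surface value of
        the slab with an impermeable electrode face and the centre-line
        pinned at n_o, starting empty —

            n(0,t) = n_o·[1 − Σ_k (2(−1)^k/((k+½)π))·exp(−(k+½)²π²·t/(4·t_D))]

        a smooth ramp from 0 saturating at n_o over a few diffusion times.
    """
    t = np.asarray(t, dtype=float)
    if mode == "prefilled":
        return n_o * np.ones_like(t)
    if mode == "front":
        k = np.arange(0, 200, dtype=float)
        coeff = 2.0 * (-1.0) ** k / ((k + 0.5) * np.pi)
        rate = (k + 0.5) ** 2 * np.pi**2 / (4.0 * t_diffusion)
        deficit = np.tensordot(coeff, np.exp(-np.multiply.outer(rate, t)), axes=1)
        # the alternating series truncates at ~1/K at t = 0, where the value
        # is exactly the initial condition
        return n_o * np.where(t == 0.0, 0.0, np.clip(1.0 - deficit, 0.0, 1.0))
    raise ValueError(f"unknown mode {mode!r}")


@dataclass
class ConcentrationField:
    """Solution of the half-channel diffusion problem on a space–time grid.

    ``n`` has shape (len(t_grid), len(x_grid)); ``surface`` is n(0, t),
    ``theta`` the monolayer coverage history, and ``flux`` the net
    adsorption flux (molecules·m⁻²·s⁻¹) actually applied at x = 0.
    """

    x_grid: np.ndarray
    t_grid: np.ndarray
    n: np.ndarray
    n_o: float
    surface: np.ndarray
    theta: np.ndarray
    flux: np.ndarray


def _stretched_grid(length: float, nodes: int, stretch: float) -> np.ndarray:
    """Geometrically stretched grid on [0, L], refined near x = 0."""
    if stretch == 1.0:
        return np.linspace(0.0, length, nodes)
    h = np.cumprod(np.full(nodes - 1, stretch))
    x = np.concatenate(([0.0], np.cumsum(h)))
    return x * (length / x[-1])


def solve_diffusion(
    diffusivity: float,
    half_height: float,
    n_o: float,
    surface_flux_law: Callable[[float, float], float] | None,
    t_grid: np.ndarray,
    x_resolution: int = 121,
    *,
    site_density: float | None = None,
    theta0: float = 0.0,
    initial: Literal["uniform", "empty"] = "uniform",
    boundary: Literal["flux", "absorbing"] = "flux",
    stretch: float = 1.05,
) -> ConcentrationField:
    """Crank–Nicolson solution of ∂n/∂t = D·∂²n/∂x² on (0, L).

    Boundary conditions: n(L, t) = n_o (Dirichlet at the centre-line) and,
    at the electrode, either a net-adsorption flux condition
    D·∂n/∂x|₀ = J(n(0,t), θ)/N_A (``boundary="flux"``) or a perfectly
    absorbing surface n(0, t) = 0 (``boundary="absorbing"``).

    ``surface_flux_law(n0, theta)`` returns the net adsorption flux in
    molecules·m⁻²·s⁻¹ given the near-surface concentration (mol/m³) and the
    current coverage.  When ``site_density`` (sites/m²) is given, the
    coverage evolves by N_s·dθ/dt = J via operator splitting per time step;
    otherwise θ stays at ``theta0``.

    Concentrations stay within [0, n_o] for admissible (purely
    adsorptive-at-equilibrium) flux laws; a negative concentration aborts
    with a diagnostic since it signals step-size trouble.
    """
    if x_resolution < 50:
        raise ValueError("x_resolution must be at least 50 nodes")
    t_grid = np.asarray(t_grid, dtype=float)
    dts = np.diff(t_grid)
    if len(dts) == 0 or np.any(dts <= 0):
        raise ValueError("t_grid must be strictly increasing")

    x = _stretched_grid(half_height, x_resolution, stretch)
    m = x_resolution
    n = np.full(m, n_o if initial == "uniform" else 0.0, dtype=float)
    n[-1] = n_o

    # nonuniform 3-point Laplacian weights for interior nodes 1..m-2
    hl = np.diff(x)[:-1]   # h_{i-1}
    hr = np.diff(x)[1:]    # h_i
    wl = 2.0 / (hl * (hl + hr))
    wr = 2.0 / (hr * (hl + hr))
    wc = -(wl + wr)

    h0 = x[1] - x[0]
    out_n = np.empty((len(t_grid), m))
    out_n[0] = n
    theta = theta0
    thetas = np.empty(len(t_grid))
    fluxes = np.empty(len(t_grid))
    surface = np.empty(len(t_grid))

    def flux_at(n0: float, th: float) -> float:
        if boundary == "absorbing" or surface_flux_law is None:
            return 0.0
        j = surface_flux_law(n0, th)
        if not np.isfinite(j):
            raise FloatingPointError("surface flux law returned non-finite value")
        return j

    thetas[0] = theta
    fluxes[0] = flux_at(n[0], theta)
    surface[0] = n[0]

    dt_prev = None
    lower = upper = diag = rhs_mat = None
    for k, dt in enumerate(dts, start=1):
        if dt != dt_prev:
            # assemble CN banded matrix for this step size
            r = 0.5 * dt * diffusivity
            diag = np.ones(m)
            lower = np.zeros(m)
            upper = np.zeros(m)
            diag[1:-1] = 1.0 - r * wc
            lower[0:-2] = -r * wl   # sub-diagonal entries for rows 1..m-2
            upper[2:] = -r * wr     # super-diagonal entries for rows 1..m-2
            rhs_mat = (r, wl, wc, wr)
            dt_prev = dt
        r, _wl, _wc, _wr = rhs_mat

        # operator split: advance coverage with current surface concentration
        j_now = flux_at(n[0], theta)
        if site_density is not None and surface_flux_law is not None:
            # explicit midpoint on the scalar coverage ODE
            th_half = theta + 0.5 * dt * flux_at(n[0], theta) / site_density
            th_half = min(max(th_half, 0.0), 1.0)
            theta = theta + dt * flux_at(n[0], th_half) / site_density
            theta = min(max(theta, 0.0), 1.0)

        rhs = n.copy()
        rhs[1:-1] = n[1:-1] + r * (_wl * n[:-2] + _wc * n[1:-1] + _wr * n[2:])

        ab = np.zeros((3, m))
        ab[0, 1:] = upper[1:]
        ab[1, :] = diag
        ab[2, :-1] = lower[:-1]

        if boundary == "absorbing":
            ab[1, 0] = 1.0
            ab[0, 1] = 0.0
            rhs[0] = 0.0
        else:
            # D·(n1 − n0)/h0 = J/N_A, J evaluated semi-implicitly at (n0_old, θ_new)
            j_bc = flux_at(n[0], theta)
            ab[1, 0] = 1.0
            ab[0, 1] = -1.0
            rhs[0] = -h0 * j_bc / (diffusivity * constants.N_A)
        # Dirichlet at x = L
        ab[1, -1] = 1.0
        ab[2, -2] = 0.0
        rhs[-1] = n_o

        n = solve_banded((1, 1), ab, rhs)
        if np.any(n < -1e-9 * max(n_o, 1.0)):
            raise FloatingPointError(
                "negative concentration: time step too large for this flux law")
        np.clip(n, 0.0, None, out=n)

        out_n[k] = n
        thetas[k] = theta
        fluxes[k] = j_now
        surface[k] = n[0]

    return ConcentrationField(x_grid=x, t_grid=t_grid, n=out_n, n_o=n_o,
                              surface=surface, theta=thetas, flux=fluxes)


def absorbing_slab_series(x: np.ndarray, t: float, half_height: float,
                          diffusivity: float, n_o: float,
                          terms: int = 2000) -> np.ndarray:
    """Eigenfunction-series solution for the slab with one absorbing face.

    n(0,t)=0, n(L,t)=n_o, n(x,0)=n_o:
    n/n_o = x/L + Σ_k (2/kπ)·sin(kπx/L)·exp(−D(kπ/L)²t).
    Used as an independent oracle for :func:`solve_diffusion`.
    """
    x = np.asarray(x, dtype=float)
    k = np.arange(1, terms + 1)[:, None]
    arg = k * np.pi / half_height
    series = (2.0 / (k * np.pi)) * np.sin(arg * x[None, :]) * \
        np.exp(-diffusivity * arg**2 * t)
    return n_o * (x / half_height + series.sum(axis=0))
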