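"""Seeded synthetic transient-induced-current experiments.

Stands in for the instrument: generates noisy multi-condition current
traces with the statistical structure the inverse analysis assumes —
equilibrium speciation, quasi-steady near-surface transport, Langmuir
surface kinetics, per-species induced-charge convolution, additive white
Gaussian noise.  Every draw is deterministic given the seed.

The default kinetics sit deliberately in the dilute low-coverage regime
(K₊γn·N_A ≪ K₋, so θ ≪ 1 over a one-second record): this is the regime in
which the measured current is linear in the species concentrations, which
is the working assumption of the mixture-superposition analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from timeskit.model_core import (
    ChannelGeometry,
    MICROMOLAR,
    NANOMOLAR,
    SpeciesParams,
    equilibrium_complex,
    flow_ul_min_to_si,
    wall_shear_stress,
)
from timeskit.surface_signal import (
    ChargeKernel,
    SignalTrace,
    SurfaceKineticsParams,
    coverage_dynamics,
    dwell_time,
    induced_current,
    langmuir_flux_constant_n,
    net_flux,
)
from timeskit.transport import diffusion_time, surface_concentration_quasisteady
from timeskit.inference import Condition, ExperimentSet

__all__ = [
    "ScenarioConfig",
    "SpeciesScenario",
    "generate_experiment_set",
    "reference_scenarios",
    "shear_sweep",
]


@dataclass(frozen=True)
class SpeciesScenario:
    """Bundle of physical, kinetic and kernel parameters for one species."""

    params: SpeciesParams
    kinetics: SurfaceKineticsParams
    bell_tau: float | None = None  # Pa; shear scale of the Bell desorption law

    def kinetics_at_shear(self, shear: float) -> SurfaceKineticsParams:
        """Bell-model desorption: K₋(τ_w) = K₋⁰·exp(τ_w/τ₀)."""
        if self.bell_tau is None or shear == 0.0:
            return self.kinetics
        return replace(self.kinetics,
                       k_minus=self.kinetics.k_minus * math.exp(shear / self.bell_tau))


@dataclass(frozen=True)
class ScenarioConfig:
    """Full description of a synthetic multi-condition experiment.

    ``design`` lists the (protein, ligand) initial concentrations (mol/m³)
    of every condition; it must include a protein-only (y = 0) and a
    ligand-only (x = 0) condition for the downstream analysis to be
    solvable.  ``snr_db`` is the signal-to-noise ratio in dB relative to
    the peak |i(t)| of the protein-only condition; ``None`` means
    noiseless.
    """

    name: str
    protein: SpeciesScenario
    ligand: SpeciesScenario
    complex: SpeciesScenario
    kd_true: float                       # mol/m³
    design: tuple[tuple[float, float], ...]
    flow_rate: float = flow_ul_min_to_si(30.0)   # m³/s
    geometry: ChannelGeometry = field(default_factory=ChannelGeometry)
    sampling_rate: float = 1000.0        # Hz
    duration: float = 1.0                # s
    snr_db: float | None = 20.0
    seed: int = 0
    transport_mode: str = "prefilled"    # or "front"

    def __post_init__(self) -> None:
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be > 0")
        if not self.duration > 0:
            raise ValueError("duration must be > 0")
        if not self.kd_true > 0:
            raise ValueError("kd_true must be > 0")
        xs = [d[0] for d in self.design]
        ys = [d[1] for d in self.design]
        if any(x < 0 or y < 0 for x, y in self.design):
            raise ValueError("design concentrations must be >= 0")
        if not any(x > 0 and y == 0 for x, y in self.design):
            raise ValueError("design must include a protein-only (y=0) condition")
        if not any(x == 0 and y > 0 for x, y in self.design):
            raise ValueError("design must include a ligand-only (x=0) condition")
        if self.transport_mode not in ("prefilled", "front"):
            raise ValueError(f"unknown transport_mode {self.transport_mode!r}")

    @property
    def n_samples(self) -> int:
        return int(round(self.sampling_rate * self.duration))

    def time_grid(self) -> np.ndarray:
        """Sample times Δt, 2Δt, …, N·Δt (flow starts at t = 0)."""
        dt = 1.0 / self.sampling_rate
        return dt * np.arange(1, self.n_samples + 1)


def _species_current(sp: SpeciesScenario, conc: float, t: np.ndarray,
                     shear: float, config: ScenarioConfig) -> np.ndarray:
    """Noiseless current contributed by one species at concentration ``conc``."""
    if conc == 0.0:
        return np.zeros_like(t)
    kin = sp.kinetics_at_shear(shear)
    gamma = sp.params.partition_gamma
    if config.transport_mode == "prefilled":
        # channel pre-filled: n(0,t) = n_o, flux has the exact closed form
        flux = langmuir_flux_constant_n(kin, gamma, conc, t)
    else:
        t_d = diffusion_time(config.geometry.half_height, sp.params.diffusivity)
        n_surf = surface_concentration_quasisteady(conc, t, t_d, mode="front")
        theta = coverage_dynamics(kin, gamma, n_surf, t)
        flux = net_flux(kin, gamma, n_surf, theta)
    trace = induced_current(sp.params.kernel, flux, t,
                            config.geometry.electrode_area)
    return trace.current


def generate_experiment_set(config: ScenarioConfig,
                            seed: int | None = None) -> ExperimentSet:
    """Simulate every condition of a scenario and return an ExperimentSet.

    Per condition: equilibrium speciation at the ground-truth K_D, then the
    three species' currents superposed, then i.i.d. Gaussian noise with a
    standard deviation set by ``snr_db`` relative to the protein-only
    signal peak (one noise level for the whole set — one instrument).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    t = config.time_grid()
    shear = wall_shear_stress(config.flow_rate, config.geometry)

    clean: list[np.ndarray] = []
    for x, y in config.design:
        eq = equilibrium_complex(x, y, config.kd_true)
        i_t = (_species_current(config.protein, eq.n_protein, t, shear, config)
               + _species_current(config.ligand, eq.n_ligand, t, shear, config)
               + _species_current(config.complex, eq.n_complex, t, shear, config))
        clean.append(i_t)

    x_only = next(i for i, (x, y) in enumerate(config.design) if x > 0 and y == 0)
    peak = float(np.max(np.abs(clean[x_only])))
    if config.snr_db is None:
        sd = 0.0
    else:
        sd = peak * 10.0 ** (-config.snr_db / 20.0)

    conditions = []
    for (x, y), i_clean in zip(config.design, clean):
        current = i_clean + (rng.normal(0.0, sd, size=i_clean.shape) if sd else 0.0)
        trace = SignalTrace(t=t.copy(), current=current, meta={
            "x_mol_m3": x, "y_mol_m3": y,
            "flow_rate_m3_s": config.flow_rate,
            "shear_pa": shear,
            "snr_db": config.snr_db,
            "noise_sd_A": sd,
            "scenario": config.name,
        })
        conditions.append(Condition(x=x, y=y, flow_rate=config.flow_rate,
                                    trace=trace))

    t_d = diffusion_time(config.geometry.half_height,
                         config.protein.params.diffusivity)
    meta = {
        "scenario": config.name,
        "kd_true": config.kd_true,
        "diffusion_time": t_d,
        # pre-filled channel: quasi-steady from the first sample; the t_D
        # exclusion applies to the front-arrival protocol
        "window_start": 0.0 if config.transport_mode == "prefilled" else t_d,
        "tau_s_protein": dwell_time(config.protein.kinetics_at_shear(shear),
                                    config.protein.params.partition_gamma, 0.0),
        "noise_sd_A": sd,
    }
    return ExperimentSet(conditions=conditions, geometry=config.geometry, meta=meta)


def shear_sweep(config: ScenarioConfig, flow_rates: Sequence[float],
                species: str = "protein", seed: int | None = None
                ) -> list[SignalTrace]:
    """Protein-only (or complex-only) traces across a flow-rate sweep.

    The desorption rate follows the Bell law K₋(τ_w) = K₋⁰·exp(τ_w/τ₀),
    so the surface dwell time shortens as the wall shear grows — the
    mechanism emulating the observed flow-rate dependence of τ_s.
    """
    if any(q <= 0 for q in flow_rates):
        raise ValueError("flow rates must be positive")
    sp = getattr(config, species)
    x_only = next((x for x, y in config.design if x > 0 and y == 0),
                  config.design[0][0])
    rng = np.random.default_rng(config.seed if seed is None else seed)
    t = config.time_grid()
    traces = []
    for q in flow_rates:
        shear = wall_shear_stress(q, config.geometry)
        i_clean = _species_current(sp, x_only, t, shear, config)
        peak = float(np.max(np.abs(i_clean)))
        sd = 0.0 if config.snr_db is None else peak * 10.0 ** (-config.snr_db / 20.0)
        current = i_clean + (rng.normal(0.0, sd, size=t.shape) if sd else 0.0)
        kin = sp.kinetics_at_shear(shear)
        traces.append(SignalTrace(t=t.copy(), current=current, meta={
            "flow_rate_m3_s": q,
            "shear_pa": shear,
            "species": species,
            "tau_s_true": dwell_time(kin, sp.params.partition_gamma, 0.0),
            "snr_db": config.snr_db,
            "scenario": config.name,
        }))
    return traces


def _default_species(name: str, diffusivity: float, kernel: ChargeKernel,
                     tau_s: float, bell_tau: float | None = None,
                     site_density: float = 3e16,
                     k_plus: float = 1e-15) -> SpeciesScenario:
    """Species preset with desorption-dominated kinetics pinned to τ_s."""
    k_minus = site_density / tau_s
    return SpeciesScenario(
        params=SpeciesParams(name=name, diffusivity=diffusivity,
                             effective_charge=0.0, partition_gamma=1.0,
                             kernel=kernel),
        kinetics=SurfaceKineticsParams(k_plus=k_plus, k_minus=k_minus,
                                       site_density=site_density),
        bell_tau=bell_tau,
    )


def reference_scenarios() -> dict[str, ScenarioConfig]:
    """Named scenario presets mirroring the published measurement designs.

    ``trypsin_paba``
        100 μM trypsin with 0/50/100/200 μM p-aminobenzamidine plus a
        ligand-only condition; ground-truth K_D = 34.7 μM (the single-run
        histogram-mode value).
    ``thermolysin_phosphoramidon``
        300 nM thermolysin with 0/150/300/600 nM phosphoramidon plus a
        ligand-only condition; ground-truth K_D = 32.1 nM (the
        replicate-averaged value).
    ``shear_sweep``
        A thermolysin-like protein/complex pair with Bell-coupled
        desorption for flow rates between 30 and 450 μL/min.

    Kernel shapes (fast dip, slower overshoot) and the relative protein /
    ligand / complex response magnitudes are free parameters of the
    emulation — chosen so the conditions separate visibly — not measured
    values.
    """
    protein_kernel = ChargeKernel(dip_amplitude=1.0e-18, dip_tau=0.010,
                                  overshoot_amplitude=1.40e-18, overshoot_tau=0.050)
    # The complex response dominates the protein's: binding is assumed to
    # rearrange the charge distribution and dipole moment strongly, which
    # is what makes the mixture conditions informative at instrument-like
    # noise.  The contrast is an emulation parameter, not a measured value.
    complex_kernel = ChargeKernel(dip_amplitude=18.0e-18, dip_tau=0.016,
                                  overshoot_amplitude=27.6e-18, overshoot_tau=0.080)
    ligand_kernel = ChargeKernel(dip_amplitude=0.04e-18, dip_tau=0.004,
                                 overshoot_amplitude=0.055e-18, overshoot_tau=0.015)

    uM, nM = MICROMOLAR, NANOMOLAR

    trypsin = ScenarioConfig(
        name="trypsin_paba",
        protein=_default_species("trypsin", 1.0e-10, protein_kernel, tau_s=3.0),
        ligand=_default_species("p-ABA", 5.0e-10, ligand_kernel, tau_s=1.0),
        complex=_default_species("trypsin/p-ABA", 9.0e-11, complex_kernel, tau_s=4.0),
        kd_true=34.7 * uM,
        design=((100 * uM, 0.0), (0.0, 200 * uM),
                (100 * uM, 50 * uM), (100 * uM, 200 * uM), (100 * uM, 100 * uM)),
        snr_db=20.0,
        seed=7,
    )

    thermolysin = ScenarioConfig(
        name="thermolysin_phosphoramidon",
        protein=_default_species("thermolysin", 7.0e-11, protein_kernel, tau_s=3.0),
        ligand=_default_species("phosphoramidon", 4.0e-10, ligand_kernel, tau_s=1.0),
        complex=_default_species("thermolysin/phosphoramidon", 6.5e-11,
                                 complex_kernel, tau_s=4.0),
        kd_true=32.1 * nM,
        design=((300 * nM, 0.0), (0.0, 600 * nM),
                (300 * nM, 150 * nM), (300 * nM, 600 * nM), (300 * nM, 300 * nM)),
        snr_db=20.0,
        seed=7,
    )

    sweep_protein_kernel = ChargeKernel(dip_amplitude=0.5e-18, dip_tau=0.008,
                                        overshoot_amplitude=1.0e-18,
                                        overshoot_tau=0.030)
    sweep_complex_kernel = ChargeKernel(dip_amplitude=0.7e-18, dip_tau=0.012,
                                        overshoot_amplitude=1.3e-18,
                                        overshoot_tau=0.040)
    sweep = ScenarioConfig(
        name="shear_sweep",
        protein=_default_species("thermolysin", 7.0e-11, sweep_protein_kernel,
                                 tau_s=0.5, bell_tau=60.0),
        ligand=_default_species("phosphoramidon", 4.0e-10, ligand_kernel,
                                tau_s=1.0),
        complex=_default_species("thermolysin/phosphoramidon", 6.5e-11,
                                 sweep_complex_kernel, tau_s=0.8, bell_tau=90.0),
        kd_true=32.1 * nM,
        design=((500 * nM, 0.0), (0.0, 500 * nM)),
        duration=2.0,
        snr_db=25.0,
        seed=7,
    )

    return {
        "trypsin_paba": trypsin,
        "thermolysin_phosphoramidon": thermolysin,
        "shear_sweep": sweep,
    }


SHEAR_SWEEP_FLOW_RATES_UL_MIN = (30.0, 60.0, 120.0, 180.0, 240.0, 300.0, 375.0, 450.0)
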