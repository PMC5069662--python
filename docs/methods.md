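# Methods

## Signal physics

The measurement this package models is a transient electrode current
produced by molecular arrival at a gold sensing pad in a microfluidic
channel. Near the electrode, within the Debye screening length (~1 nm at
typical ionic strength; `model_core.debye_length`), the interfacial field
set by the zeta potential orients an arriving molecule's dipole; the
image-charge response transfers charge between the electrode and the
amplifier. Departure drags local counter-ions away and produces an
overshoot of the opposite sign. We represent the whole single-molecule
event as an induced-charge kernel *q(t)* with q(0) = 0 and a finite
plateau, parametrised as a difference of two gamma-shaped pulses in its
derivative (fast dip, slower overshoot; `surface_signal.ChargeKernel`).
The kernel's functional form is a modelling choice — only its qualitative
morphology (dip, overshoot, recovery) is constrained by observation.

The macroscopic current is the convolution i(t) = A·d/dt(q ∗ J) with the
net molecular flux J(t) at the surface. J follows Langmuir kinetics,

    N_s·dθ/dt = K₊·γ·n(0,t)·N_A·(1−θ) − K₋·θ = J,

with K₊ an adsorption velocity (m/s), K₋ a desorption flux (1/(m²·s)),
N_s the monolayer site density (default 3×10¹⁶ m⁻²) and γ the Boltzmann
surface partition factor exp(−Ze·e·ζ/k_BT). We adopt the convention that
γ multiplies the bulk concentration (surface enhancement); since A, γ and
the kernel scale enter the observable only as products, this convention
is unidentifiable from data and the pipeline reports per-unit-
concentration responses G_i(t) rather than absolute Coulomb kernels
unless A and γ are supplied.

Transport across the half-channel (electrode at x = 0, centre-line at
x = L pinned to the bulk value) is the 1-D diffusion equation with a
flux (Robin) condition at the electrode, solved by Crank–Nicolson on an
optionally geometrically stretched grid (`transport.solve_diffusion`),
with the coverage ODE coupled by per-step operator splitting. Beyond the
diffusion time t_D = L²/(4D) — the constant 4 is a convention, exposed as
`transport.DIFFUSION_TIME_CONSTANT` — the near-surface concentration is
within a few percent of bulk, and the fast path
`surface_concentration_quasisteady` replaces the PDE: constant n_o for
the pre-filled protocol, or the closed-form cosine eigen-series of the
initially empty slab for the front-arrival variant. For constant n(0,t)
the flux is exactly J(t) = K₊γn₀N_A·e^(−t/τ_s) with the dwell time
τ_s = N_s/(K₊γn₀N_A + K₋) — the relaxation time of the adsorption
transient and the quantity the shear-sweep analysis fits.

Shear stress enters through the parallel-plate Poiseuille relation
τ_w = 6μQ/(w·h²). The default width w = 0.5 mm is calibrated so that a
30 μm tall water-filled channel gives 6.67 Pa at 30 μL/min (and hence
100 Pa at 450 μL/min); viscosity defaults to 1.0 mPa·s and temperature to
298 K. Shear-dependent desorption uses a Bell law
K₋(τ_w) = K₋⁰·exp(τ_w/τ₀) — a conventional stress-activated-escape
mechanism adopted as an emulation device, with τ₀ = 60 Pa (protein) and
90 Pa (complex) in the sweep preset so the dwell time falls severalfold
over 6.67–100 Pa.

## Equilibrium chemistry

For P + L ⇌ C with initial concentrations x, y the equilibrium complex
concentration is the smaller root of n_C² − (x+y+K_D)n_C + xy = 0,
computed in the Citardauq form 2xy/(b+√(b²−4xy)) to avoid cancellation
when K_D ≪ x, y. Units are SI (mol/m³) internally; μM/nM are accepted and
emitted at interfaces.

## Synthetic experiments

`synthetic_data.generate_experiment_set` emulates the acquisition
protocol: 1 kHz sampling over 1 s (samples at Δt…NΔt, so a one-second
record has exactly 1000 rows), a condition design containing protein-only
and ligand-only references plus mixtures, and additive white Gaussian
noise with standard deviation set by an SNR in dB relative to the peak
|i(t)| of the protein-only condition (one noise level per set — one
instrument). The reference designs mirror the published protocols:
100 μM trypsin with 0/50/100/200 μM p-aminobenzamidine (ground-truth
K_D = 34.7 μM) and 300 nM thermolysin with 0/150/300/600 nM
phosphoramidon (K_D = 32.1 nM), each augmented with a ligand-only
condition at the maximum ligand concentration so the unit responses are
measurable.

Default kinetics sit deliberately in the dilute low-coverage regime
(K₊γnN_A/K₋ ≲ 10⁻⁷, θ ≪ 1 over one second): the measured current is then
linear in the species concentrations, which is precisely the regime the
mixture-superposition analysis assumes. Preset dwell times are ~3–4 s, so
the dwell-time decay term is mild within the one-second analysis record.

Free emulation parameters the data cannot pin down are chosen once and
documented: the ligand response is small but nonzero (small molecules
carry small dipoles; a silent-ligand variant is a config change away),
and the complex kernel is both reshaped and strongly amplified relative
to the protein's (~12× amplitude). The premise of the measurement is that
binding alters the charge distribution and dipole moment appreciably; the
amplitude contrast sets how strongly the binding signature stands above
the noise floor in the mixtures, and the default makes the four
conditions separate clearly at SNR 20 dB. It is an emulation choice, not
a measured value.

What the generator does **not** emulate: amplifier transfer functions and
filtering, electrode fouling and drift, temperature fluctuations,
non-Gaussian interference, advection and Taylor dispersion. Passing
recovery tests on these synthetic sets therefore demonstrates the
correctness and noise robustness of the inversion under the model's own
assumptions — not robustness to instrument systematics.

## Inverse analyses

**Unit responses.** G_P(t) = i_P(t)/x and G_L(t) = i_L(t)/y from the
single-species conditions.

**Per-timepoint K_D.** Writing a_j(t) = i_j(t) − x_j·G_P − y_j·G_L for
mixture j, the elimination of G_C(t) between two mixtures reduces, per
timepoint, to matching the complex-concentration ratio:

    n_C2(K_D)/n_C1(K_D) = a₂(t)/a₁(t),

a one-dimensional root problem solved by a 64-point log-spaced pre-scan
over K_D ∈ [1 pM, 10 mM] followed by Brent refinement on each sign
change. The ratio ρ(K_D) is monotone between its limits
min(x₂,y₂)/min(x₁,y₁) and x₂y₂/(x₁y₁), so multiple roots indicate a
degenerate timepoint and are flagged; roots at the bracket edge, ratios
outside the attainable range (no sign change), and timepoints where
a₁ ≈ 0 (no complex information — the complex signature crosses zero) are
all discarded with per-flag counts reported. These failures are exactly
the noise spikes visible in a K_D-versus-time trace. By default the
complex-richest mixture (largest min(x, y)) is the eliminating condition
and the leanest the residual one — the canonical 1:2 / 2:1 pair.

**Analysis window.** Timepoints are solved at every sample; the histogram
retains those with t ≥ window_start and t ≤ c·τ̂_s (c = 0.5), where τ̂_s
is fitted from the protein-only trace. window_start is 0 for the
pre-filled protocol (quasi-steady from the first sample) and t_D for the
front-arrival protocol. If the dwell-time fit is unreliable and its cap
would leave fewer than `min_samples` (50) estimates, the cap disengages
and the full record is used (reported in diagnostics).

**Histogram mode.** Retained samples are binned into 50 log₁₀-spaced bins
at fixed edges spanning the search bracket, and the estimate is the
geometric mean of the samples in the highest-count bin and its immediate
neighbours (ties break toward the lower bin). Fixed edges make the
estimator deterministic in everything but the data (edges tied to sample
extremes jitter from realisation to realisation), the one-bin
neighbourhood makes it robust to the modal lump straddling an edge, and
the geometric mean is the natural location statistic on a log grid. The
spread of the retained samples (IQR in log₁₀) is the built-in quality
indicator: designs outside the recommended 0.1·K_D < x, y < 10·K_D window
show a visibly broadened histogram. At instrument-like noise the
practical floor for measurable dissociation constants is of order 1 nM,
surfaced as a diagnostic rather than enforced as a limit.

**Dwell-time fit.** A single exponential A₀e^(−t/τ)+c is fitted to the
post-peak relaxation: the segment starts at the extremum whose sign
matches the tail (the overshoot peak for a biphasic trace), and a second
pass drops the first half-τ̂ of the segment where the faster kernel
transients still contaminate the tail. Non-positive τ, non-finite or
dominant standard errors, and τ beyond 50× the fitted span are flagged
failures, never silent values. Whether τ_s should be fitted from i(t)
tails or from deconvolved q(t) tails is genuinely open; both are
available and the default is the i(t) relaxation.

**Kernel deconvolution.** Q(t) (cumulative trapezoid of the current) is
inverted through the lower-triangular convolution operator by Tikhonov
regularisation with a second-difference smoothness penalty plus a 1%
ridge (curvature penalties alone leave linear ramps unpenalised), scaled
relative to the data term. Output is normalised to unit peak; residual
norm and condition number are reported, with a warning flag past 10¹².

## Numerical choices

- Coverage ODE: LSODA at rtol 10⁻¹⁰ / atol 10⁻¹³; matches the closed-form
  Langmuir relaxation to better than 10⁻⁶ relative at constant
  concentration.
- Diffusion: Crank–Nicolson, banded solves; 201 nodes and Δt = 5×10⁻⁴ s
  reproduce the absorbing-slab eigen-series to <0.1% at interior nodes;
  discrete mass bookkeeping closes to <0.5%.
- Convolution: trapezoid end-point weights; the impulse path
  A·(q̇ ∗ J) and the charge path d/dt[A·(q ∗ J)] agree to the
  discretisation order and both are exercised in tests.
- Root finding: Brent with rtol 10⁻¹⁴ — the noiseless forward–inverse
  round trip recovers the generating K_D to ~10⁻⁶ relative at every
  informative timepoint.
- Problem sizes: reference analyses use 1000-sample records and
  five-condition sets; a full generate-plus-invert cycle runs in well
  under a second, and the deconvolution (dense 1000×1000 normal
  equations) in under a second.

## Known limitations

- K_D precision degrades when the design leaves the recommended
  concentration window or when the complex response is close to the sum
  of its parts (a₁ → 0 at all times makes the problem unidentifiable).
- The dwell-time fit assumes a single dominant relaxation; strongly
  overlapping kernel and surface timescales bias it (the sweep presets
  keep kernel time constants ≳ 10× faster than τ_s).
- The generator's linear-response default means saturation effects
  (θ approaching 1, concentration-dependent τ_s) are present in the
  model but deliberately weak in the presets; analyses of
  saturation-regime data would need the PDE/ODE path and would violate
  the mixture superposition the K_D solver assumes.
- Replicate uncertainty is the sample standard deviation over repeated
  experiment sets; no posterior inference is attempted.
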