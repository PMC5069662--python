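# timeskit

Forward modelling and inverse analysis of **transient induced molecular
electronic signals**: the label-free, immobilization-free detection of
protein–ligand binding from the transient current a molecule induces on a
microfluidic gold electrode as it arrives, reorients its dipole, and
departs.

The package is aimed at people developing or studying this class of
measurement — it simulates realistic multi-condition signal sets in place
of the instrument, and implements the full inverse pipeline that turns
raw current traces into a per-molecule charge kernel *q(t)*, a surface
dwell time *τ_s*, and an equilibrium dissociation constant *K_D*.

## The model

A molecule reaching the electrode induces a charge impulse response
*q(t)* (Coulomb); the net electrode charge is the convolution with the
molecular flux *J(t)* over electrode area *A*:

    Q(t) = A ∫₀ᵗ q(t−t′) J(t′) dt′,          i(t) = dQ/dt .

The flux follows Langmuir adsorption/desorption on a monolayer of *N_s*
sites, fed by 1-D diffusion across the half-channel (electrode at *x* = 0,
centre-line concentration pinned at *n_o*):

    N_s dθ/dt = K₊ γ n(0,t) (1−θ) − K₋ θ = J(t),
    ∂n/∂t = D ∂²n/∂x²,    n(L,t) = n_o,

with γ = exp(−Ze·e·ζ/k_BT) the electrostatic surface partition factor.
For times beyond the diffusion time *t_D = L²/4D* the near-surface
concentration is ≈ *n_o* and the flux relaxes exponentially with the
dwell time τ_s = N_s/(K₊γn_o·N_A + K₋).

In a mixture at binding equilibrium (P + L ⇌ C, n_P·n_L = K_D·n_C) the
current superposes per species:

    i(t) = n_P G_P(t) + n_L G_L(t) + n_C G_C(t),

where *G_i(t)* is the per-unit-concentration response of species *i*.
Measuring four-plus conditions (protein only, ligand only, and two
protein/ligand ratios) pins *G_P* and *G_L* from the single-species
conditions; eliminating *G_C(t)* between two mixtures leaves one scalar
equation in *K_D* per timepoint, solved by bracketed root search over
log₁₀K_D. A 1 kHz × 1 s record yields 1000 per-timepoint estimates;
noise-driven spikes are rejected and the histogram mode of the retained
samples is the reported *K_D*.

## Worked example

Simulate the trypsin / p-aminobenzamidine reference scenario (100 μM
protein with 0/50/100/200 μM ligand plus a ligand-only condition,
ground-truth K_D = 34.7 μM, 1 kHz over 1 s, SNR 20 dB) and run the
inversion:

```sh
$ timeskit simulate --scenario trypsin_paba --seed 7 --out demo/
INFO times: wrote 5 traces and manifest.yaml to demo
$ timeskit infer --manifest demo/manifest.yaml --out demo/result.json
INFO times: kd_mode = 0.0344527 mol/m^3 (34.4527 uM); retained 978/1000 timepoints
```

The recovered modal K_D is 34.45 μM — within 0.8% of the generating
34.7 μM; 978 of the 1000 per-timepoint estimates survived outlier
filtering (the rest are the noise spikes the histogram discards).
`demo/result.json` holds the K_D samples, the histogram, per-condition
dwell-time fits and full provenance (scenario, seed, software version).

The same from Python:

```python
from timeskit import run_kd_pipeline
from timeskit.synthetic_data import generate_experiment_set, reference_scenarios

cfg = reference_scenarios()["thermolysin_phosphoramidon"]  # K_D = 32.1 nM
result = run_kd_pipeline(generate_experiment_set(cfg, seed=7))
print(result.kd_mode * 1e6)   # → 32.70 nM
```

`timeskit fit-tau --trace trace.csv` fits the surface dwell time of
individual traces (the shear-stress sweep analysis), and
`timeskit validate --manifest …` checks an experiment manifest against
the schema and the condition-design requirements.

## Layout

- `timeskit.model_core` — binding equilibrium, Boltzmann surface
  partition, Poiseuille wall shear, Debye length
- `timeskit.transport` — half-channel diffusion (Crank–Nicolson) and the
  quasi-steady near-surface concentration
- `timeskit.surface_signal` — Langmuir surface kinetics, charge kernels,
  the flux → current forward map, mixture superposition
- `timeskit.inference` — kernel deconvolution, dwell-time fitting,
  per-timepoint K_D extraction, histogram-mode estimation
- `timeskit.synthetic_data` — seeded scenario generator and presets
- `timeskit.io` / `timeskit.cli` — CSV traces, YAML manifests, JSON
  results, command-line entry points

See `docs/methods.md` for the modelling assumptions, parameter defaults
and numerical choices.
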