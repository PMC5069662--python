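import math
from dataclasses import replace

import numpy as np
import pytest

from timeskit.inference import (
    PipelineConfig,
    deconvolve_kernel,
    fit_adsorption_time,
    kd_histogram_mode,
    run_kd_pipeline,
    run_kd_replicates,
    solve_kd_timepoint,
    unit_responses_from_singles,
)
from timeskit.surface_signal import ChargeKernel, SignalTrace, induced_current
from timeskit.synthetic_data import generate_experiment_set


class TestUnitResponses:
    def test_recovers_known_response_exactly(self, rng):
        t = np.arange(0, 500) * 1e-3
        g = rng.normal(0, 1, len(t))
        tr_p = SignalTrace(t=t, current=0.1 * g)
        tr_l = SignalTrace(t=t, current=0.2 * g)
        gp, gl = unit_responses_from_singles(tr_p, 0.1, tr_l, 0.2)
        assert np.allclose(gp, g)
        assert np.allclose(gl, g)

    def test_unit_response_invariant_to_concentration(self, rng):
        t = np.arange(0, 500) * 1e-3
        g = rng.normal(0, 1, len(t))
        for x in (0.05, 0.1):
            tr = SignalTrace(t=t, current=x * g)
            gp, _ = unit_responses_from_singles(
                tr, x, SignalTrace(t=t, current=g), 1.0)
            assert np.allclose(gp, g)

    def test_zero_concentration_rejected(self):
        t = np.arange(0, 100) * 1e-3
        tr = SignalTrace(t=t, current=np.zeros_like(t))
        with pytest.raises(ValueError):
            unit_responses_from_singles(tr, 0.0, tr, 1.0)


class TestSolveKdTimepoint:
    X1, Y1, X2, Y2 = 0.1, 0.2, 0.1, 0.05  # 1:2 and 2:1 designs, mol/m³

    def _signals(self, kd, gp=2.0, gl=0.1, gc=30.0):
        from timeskit.model_core import equilibrium_complex
        out = []
        for x, y in ((self.X1, self.Y1), (self.X2, self.Y2)):
            eq = equilibrium_complex(x, y, kd)
            out.append(eq.n_protein * gp + eq.n_ligand * gl + eq.n_complex * gc)
        return out[0], out[1], gp, gl, gc

    @pytest.mark.parametrize("kd_true", [34.7e-3, 32.1e-6, 1e-2, 1e-5])
    def test_noiseless_root_recovers_generating_kd(self, kd_true):
        i1, i2, gp, gl, gc = self._signals(kd_true)
        kd, g_c, flag = solve_kd_timepoint(i1, i2, gp, gl,
                                           self.X1, self.Y1, self.X2, self.Y2)
        assert flag == ""
        assert kd == pytest.approx(kd_true, rel=1e-9)
        assert g_c == pytest.approx(gc, rel=1e-6)

    def test_scale_invariance(self):
        i1, i2, gp, gl, _ = self._signals(34.7e-3)
        kd_a, _, _ = solve_kd_timepoint(i1, i2, gp, gl,
                                        self.X1, self.Y1, self.X2, self.Y2)
        c = 7.3e5
        kd_b, _, _ = solve_kd_timepoint(c * i1, c * i2, c * gp, c * gl,
                                        self.X1, self.Y1, self.X2, self.Y2)
        assert kd_b == pytest.approx(kd_a, rel=1e-12)

    def test_ligand_free_mixtures_rejected_as_degenerate(self):
        with pytest.raises(ValueError):
            solve_kd_timepoint(1.0, 2.0, 1.0, 1.0, 0.1, 0.0, 0.2, 0.0)

    def test_identical_mixtures_rejected(self):
        with pytest.raises(ValueError):
            solve_kd_timepoint(1.0, 2.0, 1.0, 1.0, 0.1, 0.2, 0.1, 0.2)

    def test_no_complex_information_flagged(self):
        # i values consistent with zero complex signal: a1 = 0
        gp, gl = 2.0, 0.1
        i1 = self.X1 * gp + self.Y1 * gl
        kd, _, flag = solve_kd_timepoint(i1, 1.0, gp, gl,
                                         self.X1, self.Y1, self.X2, self.Y2)
        assert flag == "degenerate"
        assert math.isnan(kd)

    def test_inconsistent_ratio_flagged_no_root(self):
        # target ratio far outside the attainable range of n_C2/n_C1
        gp, gl = 2.0, 0.1
        a1, a2 = 1.0, 100.0  # ratio 100 ≫ max attainable
        i1 = self.X1 * gp + self.Y1 * gl + a1
        i2 = self.X2 * gp + self.Y2 * gl + a2
        kd, _, flag = solve_kd_timepoint(i1, i2, gp, gl,
                                         self.X1, self.Y1, self.X2, self.Y2)
        assert flag in ("no_root", "edge")
        assert math.isnan(kd)


class TestKdHistogramMode:
    def test_identical_samples_return_that_value(self):
        v = 34.7e-3
        _, _, mode = kd_histogram_mode(np.full(200, v))
        assert mode == pytest.approx(v, rel=1e-12)

    def test_robust_to_large_spike_outliers(self, rng):
        v = 34.7e-3
        good = v * np.exp(rng.normal(0, 0.05, 950))
        spikes = v * 100 * np.exp(rng.normal(0, 0.1, 50))
        _, _, mode = kd_histogram_mode(np.concatenate([good, spikes]))
        assert mode == pytest.approx(v, rel=0.1)

    def test_too_few_samples_raise_with_count(self):
        with pytest.raises(ValueError, match="10"):
            kd_histogram_mode(np.ones(10))

    def test_nan_samples_excluded(self):
        v = 1e-4
        samples = np.concatenate([np.full(100, v), np.full(100, np.nan)])
        _, _, mode = kd_histogram_mode(samples)
        assert mode == pytest.approx(v, rel=1e-12)


class TestFitAdsorptionTime:
    def test_pure_exponential_exact(self):
        t = np.arange(1, 2001) * 1e-3
        y = 2.5 * np.exp(-t / 0.3) + 0.1
        fit = fit_adsorption_time((t, y))
        assert fit.ok
        assert fit.tau == pytest.approx(0.3, rel=1e-6)

    def test_negative_going_exponential(self):
        t = np.arange(1, 2001) * 1e-3
        y = -1.5 * np.exp(-t / 0.2)
        fit = fit_adsorption_time((t, y))
        assert fit.ok
        assert fit.tau == pytest.approx(0.2, rel=1e-6)

    def test_white_noise_flagged_failure(self, rng):
        t = np.arange(1, 2001) * 1e-3
        fit = fit_adsorption_time((t, rng.normal(0, 1, len(t))))
        assert not fit.ok
        assert not math.isnan(fit.tau) or fit.message

    def test_biphasic_trace_recovers_relaxation_time(self):
        # forward model: biphasic kernel convolved with exponential flux
        kern = ChargeKernel(0.5e-18, 0.008, 1.0e-18, 0.030)
        t = np.arange(1, 2001) * 1e-3
        tau_true = 0.3
        flux = 5e16 * np.exp(-t / tau_true)
        tr = induced_current(kern, flux, t, 1e-6)
        fit = fit_adsorption_time(tr)
        assert fit.ok
        assert fit.tau == pytest.approx(tau_true, rel=0.03)


class TestDeconvolveKernel:
    KERN = ChargeKernel(1.0e-18, 0.010, 1.4e-18, 0.050)

    def _forward(self, t, tau_j=0.5):
        flux = 5e16 * np.exp(-t / tau_j)
        return induced_current(self.KERN, flux, t, 1e-6), flux

    def test_round_trip_at_30_db(self, rng):
        t = np.arange(1, 1001) * 1e-3
        tr, flux = self._forward(t)
        sd = np.abs(tr.current).max() * 10 ** (-30 / 20)
        noisy = SignalTrace(t=t, current=tr.current + rng.normal(0, sd, len(t)))
        q, diag = deconvolve_kernel(noisy, flux, 1e-6, regularization=1e-4)
        template = self.KERN.q(t - t[0])
        template = template / np.abs(template).max()
        rms = np.sqrt(np.mean((q - template) ** 2))
        assert rms < 0.05

    def test_round_trip_error_decreases_with_snr(self, rng):
        t = np.arange(1, 1001) * 1e-3
        tr, flux = self._forward(t)
        template = self.KERN.q(t - t[0])
        template = template / np.abs(template).max()
        errors = []
        for snr in (10, 20, 30, 40):
            sd = np.abs(tr.current).max() * 10 ** (-snr / 20)
            noisy = SignalTrace(t=t,
                                current=tr.current + rng.normal(0, sd, len(t)))
            q, _ = deconvolve_kernel(noisy, flux, 1e-6, regularization=1e-4)
            errors.append(np.sqrt(np.mean((q - template) ** 2)))
        assert all(a > b for a, b in zip(errors, errors[1:]))

    def test_strong_regularization_shrinks_kernel(self):
        t = np.arange(1, 501) * 1e-3
        tr, flux = self._forward(t)
        _, diag_small = deconvolve_kernel(tr, flux, 1e-6, regularization=1e-6)
        _, diag_large = deconvolve_kernel(tr, flux, 1e-6, regularization=1e9)
        assert diag_large["peak_abs"] < 1e-3 * diag_small["peak_abs"]

    def test_zero_flux_rejected(self):
        t = np.arange(1, 101) * 1e-3
        tr = SignalTrace(t=t, current=np.ones_like(t))
        with pytest.raises(ValueError):
            deconvolve_kernel(tr, np.zeros_like(t), 1e-6)


class TestPipeline:
    def test_noiseless_mode_equals_generating_kd(self, trypsin_noiseless):
        cfg, exp = trypsin_noiseless
        res = run_kd_pipeline(exp)
        assert res.kd_mode == pytest.approx(cfg.kd_true, rel=1e-4)

    def test_scale_invariance_of_kd_samples(self, trypsin_noiseless):
        cfg, exp = trypsin_noiseless
        res_a = run_kd_pipeline(exp)
        from timeskit.inference import Condition, ExperimentSet
        scaled = ExperimentSet(
            conditions=[Condition(c.x, c.y, c.flow_rate,
                                  c.trace.copy_with(c.trace.current * 37.5))
                        for c in exp.conditions],
            geometry=exp.geometry, meta=dict(exp.meta))
        res_b = run_kd_pipeline(scaled)
        a, b = res_a.kd_samples, res_b.kd_samples
        both = np.isfinite(a) & np.isfinite(b)
        assert np.allclose(a[both], b[both], rtol=1e-9)
        assert (np.isfinite(a) == np.isfinite(b)).all()

    def test_histogram_spread_grows_with_noise(self, scenarios):
        cfg = scenarios["trypsin_paba"]
        iqrs = []
        for snr in (40, 30, 20, 10):
            exp = generate_experiment_set(replace(cfg, snr_db=snr), seed=11)
            res = run_kd_pipeline(exp)
            q1, q3 = np.quantile(np.log10(res.kd_retained), [0.25, 0.75])
            iqrs.append(q3 - q1)
        assert all(a <= b + 1e-12 for a, b in zip(iqrs, iqrs[1:]))

    def test_missing_single_conditions_rejected(self, trypsin_noiseless):
        from timeskit.inference import ExperimentSet
        _, exp = trypsin_noiseless
        no_ligand_only = ExperimentSet(
            conditions=[c for c in exp.conditions if c.x > 0],
            geometry=exp.geometry, meta=dict(exp.meta))
        with pytest.raises(ValueError):
            run_kd_pipeline(no_ligand_only)

    def test_replicates_mean_and_sd(self, scenarios):
        cfg = scenarios["trypsin_paba"]
        sets = [generate_experiment_set(cfg, seed=s) for s in (1, 2, 3)]
        mean, sd, results = run_kd_replicates(sets)
        assert len(results) == 3
        assert mean == pytest.approx(cfg.kd_true, rel=0.10)
        assert sd < 0.15 * mean

    def test_histogram_broadens_outside_recommended_window(self, scenarios):
        # concentrations ~100× K_D carry almost no K_D information: the
        # complex ratio saturates, so the sample spread grows visibly
        cfg = scenarios["trypsin_paba"]
        res_good = run_kd_pipeline(generate_experiment_set(cfg, seed=4))
        cfg_far = replace(cfg, kd_true=cfg.kd_true / 100.0)
        res_far = run_kd_pipeline(generate_experiment_set(cfg_far, seed=4))

        def log_iqr(r):
            q1, q3 = np.quantile(np.log10(r.kd_retained), [0.25, 0.75])
            return q3 - q1

        assert log_iqr(res_far) > 3 * log_iqr(res_good)

    def test_diagnostics_account_for_every_timepoint(self, trypsin_noiseless):
        _, exp = trypsin_noiseless
        res = run_kd_pipeline(exp)
        d = res.diagnostics
        assert d["n_timepoints"] == len(exp.t)
        n_flagged = sum(d["flags"].values())
        assert n_flagged == d["n_solver_failures"]
        assert np.sum(np.isfinite(res.kd_samples)) == \
            d["n_timepoints"] - d["n_solver_failures"]
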