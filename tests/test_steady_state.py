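"""Steady-state two-pool model, R1f constraint, B1/B0 handling and fitting."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from nmmt import synth
from nmmt.physics import SaturationPoint, TwoPoolParams, rate_Wf, rate_Wr, uT_to_rad_per_s
from nmmt.presets import LC_SUBJECT1, SN_MEAN
from nmmt.steady_state import (
    QmtFitConfig,
    ZSpectrum,
    _starts,
    apply_b1_b0,
    constrain_R1f,
    fit_z_spectrum,
    mz_steady_state,
    t1_obs_from_params,
)


def ode_plateau_oracle(params: TwoPoolParams, point: SaturationPoint, t_end: float = 40.0) -> float:
    """Long-time plateau of the coupled longitudinal equations under
    continuous saturation (normalized per-pool coordinates)."""
    Wr = rate_Wr(point, params.T2r)
    Wf = rate_Wf(point, params.T2f)
    kfr, krf = params.kfr, params.krf

    def rhs(t, y):
        mzf, mzr = y
        return [
            params.R1f * (1 - mzf) - kfr * mzf + kfr * mzr - Wf * mzf,
            params.R1r * (1 - mzr) - krf * mzr + krf * mzf - Wr * mzr,
        ]

    sol = solve_ivp(rhs, (0.0, t_end), [1.0, 1.0], rtol=1e-10, atol=1e-12)
    return float(sol.y[0, -1])


class TestForwardModel:
    def test_zero_amplitude_is_unity(self, lc1_params):
        assert mz_steady_state(lc1_params, SaturationPoint(0.0, 1280.0)) == 1.0

    def test_far_off_resonance_limit(self, lc1_params):
        for amp in (1.0, 4.0, 7.0):
            pt = SaturationPoint.from_uT(amp, 1e6)
            assert mz_steady_state(lc1_params, pt) > 0.999

    def test_monotone_nonincreasing_in_amplitude(self, lc1_params):
        for delta in synth.PAPER_OFFSETS_HZ:
            vals = [
                mz_steady_state(lc1_params, SaturationPoint.from_uT(a, delta))
                for a in np.linspace(0.0, 7.0, 15)
            ]
            assert np.all(np.diff(vals) <= 1e-12)
            assert 0.0 < min(vals) <= 1.0

    def test_matches_ode_plateau_oracle_lc(self, lc1_params):
        pt = SaturationPoint.from_uT(0.153, 1280.0)
        want = ode_plateau_oracle(lc1_params, pt)
        assert mz_steady_state(lc1_params, pt) == pytest.approx(want, rel=1e-3)

    def test_ode_plateau_equivalence_grid(self, lc1_params):
        # 5x5 amplitude x offset grid
        for amp in np.linspace(0.5, 2.5, 5):
            for delta in np.geomspace(210.0, 10000.0, 5):
                pt = SaturationPoint.from_uT(amp, delta)
                want = ode_plateau_oracle(lc1_params, pt)
                got = mz_steady_state(lc1_params, pt)
                assert got == pytest.approx(want, rel=1e-3)


class TestConstrainR1f:
    def test_decoupled_pools(self):
        assert constrain_R1f(1.56, R1r=1.0, krf=1e-12, f=0.05) == pytest.approx(
            1.0 / 1.56, rel=1e-9
        )

    def test_equal_rate_pools(self):
        # when R1r already equals the observed rate, exchange is invisible
        got = constrain_R1f(1.56, R1r=1.0 / 1.56, krf=7.03, f=0.0493)
        assert got == pytest.approx(1.0 / 1.56, rel=1e-9)

    def test_matches_eigenvalue_grid_search_oracle(self):
        t1_obs, R1r, krf, f = 1.56, 1.0, 7.03, 0.0493
        target = 1.0 / t1_obs

        def slow_eig(R1f):
            kfr = f * krf
            A = np.array([[-(R1f + kfr), kfr], [krf, -(R1r + krf)]])
            return float(np.max(np.linalg.eigvals(A).real))  # least negative

        # progressive grid refinement, independent of the root finder
        lo, hi = 1e-3, 20.0
        for _ in range(8):
            grid = np.linspace(lo, hi, 1001)
            errs = [abs(-slow_eig(r) - target) for r in grid]
            i = int(np.argmin(errs))
            lo, hi = grid[max(i - 1, 0)], grid[min(i + 1, 1000)]
        oracle = grid[i]
        got = constrain_R1f(t1_obs, R1r, krf, f)
        assert got == pytest.approx(oracle, abs=1e-6)
        # contract: slow recovery eigenvalue equals 1/t1_obs
        assert -slow_eig(got) == pytest.approx(target, abs=1e-9)

    def test_no_root_reports_bracket(self):
        with pytest.raises(ValueError, match="slow recovery"):
            # observed rate faster than any achievable slow eigenvalue
            constrain_R1f(0.04, R1r=1.0, krf=7.0, f=0.05)


class TestB1B0:
    def test_identity(self):
        pt = SaturationPoint.from_uT(6.74, 1280.0)
        out = apply_b1_b0(pt, 1.0, 0.0)
        assert out.omega1_cwpe == pt.omega1_cwpe and out.delta == pt.delta

    def test_scale_and_shift(self):
        pt = SaturationPoint.from_uT(6.74, 1280.0)
        out = apply_b1_b0(pt, 0.9, -30.0)
        assert out.b1_uT == pytest.approx(6.066, rel=1e-12)
        assert out.delta == 1250.0

    def test_roundtrip(self):
        pt = SaturationPoint.from_uT(2.215, 860.0)
        back = apply_b1_b0(apply_b1_b0(pt, 1.13, 42.0), 1.13, 42.0, inverse=True)
        assert back.omega1_cwpe == pytest.approx(pt.omega1_cwpe, rel=1e-12)
        assert back.delta == pytest.approx(pt.delta, abs=1e-12)

    def test_out_of_range_scale(self):
        with pytest.raises(ValueError):
            apply_b1_b0(SaturationPoint(1.0, 860.0), 2.0, 0.0)


class TestFitZSpectrum:
    def test_noiseless_recovery_lc_subject(self):
        spec, _ = synth.make_z_spectra(LC_SUBJECT1.params(), roi_label="LC")
        fit = fit_z_spectrum(spec)
        assert fit.estimates["f"] * 100.0 == pytest.approx(4.93, abs=0.05)
        assert fit.estimates["krf"] == pytest.approx(7.03, rel=0.01)
        assert fit.estimates["T2f"] * 1e3 == pytest.approx(154.46, rel=0.01)
        assert fit.estimates["T2r"] * 1e6 == pytest.approx(10.75, rel=0.01)
        assert fit.converged

    def test_noiseless_recovery_all_roi_means(self, roi_presets):
        for name, preset in roi_presets.items():
            spec, _ = synth.make_z_spectra(preset.params(), roi_label=name)
            fit = fit_z_spectrum(spec)
            assert fit.estimates["f"] * 100 == pytest.approx(preset.f_percent, rel=0.01)
            assert fit.estimates["krf"] == pytest.approx(preset.krf_hz, rel=0.01)
            assert fit.estimates["T2f"] * 1e3 == pytest.approx(preset.t2f_ms, rel=0.01)
            assert fit.estimates["T2r"] * 1e6 == pytest.approx(preset.t2r_us, rel=0.01)

    def test_fixed_point_at_multistart_start(self):
        # data generated exactly at one of the optimizer's own starting
        # vectors must be refitted to that vector with zero residual
        cfg = QmtFitConfig()
        x0 = _starts(cfg)[0]
        f, krf, t2f, t2r = x0
        params = TwoPoolParams(
            R1f=constrain_R1f(1.2, cfg.R1r, krf, f), R1r=cfg.R1r,
            T2f=t2f, T2r=t2r, krf=krf, f=f,
        )
        amps, offs, vals = [], [], []
        for a in synth.default_cwpe_uT():
            for d in synth.PAPER_OFFSETS_HZ:
                amps.append(a); offs.append(d)
                vals.append(mz_steady_state(params, SaturationPoint(uT_to_rad_per_s(a), d)))
        spec = ZSpectrum("toy", np.array(amps), np.array(offs), np.array(vals), t1_obs=1.2)
        fit = fit_z_spectrum(spec, cfg)
        assert fit.rss < 1e-20
        assert np.allclose(list(fit.estimates.values()), x0, rtol=1e-6)

    def test_monte_carlo_recovery_sn_roi_mean(self):
        # voxel SNR 50 with the SN ROI's 404-voxel averaging; median
        # recovered pool size ratio within 10% of the generative value
        params = SN_MEAN.params()
        errs = []
        for seed in range(100):
            spec, _ = synth.make_z_spectra(
                params, noise_sd=0.02, n_averages=404, seed=seed, roi_label="SN"
            )
            fit = fit_z_spectrum(spec)
            errs.append(abs(fit.estimates["f"] * 100 / SN_MEAN.f_percent - 1.0))
        assert np.median(errs) < 0.10

    def test_too_few_samples_rejected(self):
        spec = ZSpectrum("x", [1, 1, 1], [210, 430, 860], [0.5, 0.6, 0.7], t1_obs=1.2)
        with pytest.raises(ValueError, match="at least 6"):
            fit_z_spectrum(spec)

    def test_fitted_model_monotone_in_amplitude(self):
        # forward-model monotonicity holds at the fitted parameter set
        spec, _ = synth.make_z_spectra(SN_MEAN.params(), noise_sd=0.005, n_averages=50, seed=5)
        fit = fit_z_spectrum(spec)
        for delta in synth.PAPER_OFFSETS_HZ:
            vals = [
                mz_steady_state(fit.params, SaturationPoint.from_uT(a, delta))
                for a in np.linspace(0.0, 7.0, 10)
            ]
            assert np.all(np.diff(vals) <= 1e-12)


def test_t1_obs_inverts_constraint(lc1_params):
    assert t1_obs_from_params(lc1_params) == pytest.approx(1.56, rel=1e-9)
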