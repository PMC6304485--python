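"""Segmented IVIM and R2* fitter behaviour: exact recovery, oracles, robustness."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ivimr2 import (
    FitConfig,
    IvimParameters,
    RelaxometryParameters,
    SignalCurve,
    add_rician_noise,
    fit_ivim_segmented,
    fit_monoexponential,
    fit_r2star,
    generate_curve,
    ivim_signal,
)
from ivimr2.fitting import FitError
from tests.conftest import CONTROL_R2STAR


class TestMonoexponential:
    def test_exact_on_noise_free_decay(self):
        b = np.array([200.0, 400.0, 600.0, 800.0, 1000.0])
        y = np.exp(-b * 1.0e-3)
        curve = SignalCurve(tuple(b), tuple(y), "diffusion")
        d, intercept, rss, n = fit_monoexponential(curve)
        assert d == pytest.approx(1.0e-3, rel=1e-12)
        assert intercept == pytest.approx(1.0, rel=1e-12)
        assert rss == pytest.approx(0.0, abs=1e-20)
        assert n == 5

    def test_constant_curve_zero_decay(self):
        curve = SignalCurve((0.0, 100.0, 200.0), (5.0, 5.0, 5.0), "diffusion")
        d, intercept, _, _ = fit_monoexponential(curve)
        assert d == pytest.approx(0.0, abs=1e-15)
        assert intercept == pytest.approx(5.0)

    def test_nonpositive_points_excluded(self):
        curve = SignalCurve((0.0, 100.0, 200.0, 300.0), (1.0, 0.9, 0.0, 0.8), "diffusion")
        *_, n = fit_monoexponential(curve)
        assert n == 3

    def test_too_few_points_raises(self):
        curve = SignalCurve((0.0, 100.0), (1.0, 0.0), "diffusion")
        with pytest.raises(FitError):
            fit_monoexponential(curve)


class TestSegmentedIvim:
    def test_control_row_recovery(self, control_dwi_curve, control_params):
        res = fit_ivim_segmented(control_dwi_curve)
        assert res.converged
        assert res.params.D == pytest.approx(control_params.D, rel=1e-3)
        assert res.params.f == pytest.approx(control_params.f, rel=1e-3)
        assert res.params.D_star == pytest.approx(control_params.D_star, rel=1e-3)
        assert res.n_points_used == {"low_b": 6, "high_b": 5}

    def test_pure_monoexponential_gives_zero_perfusion(self, protocol):
        p = IvimParameters(D=1.1e-3, D_star=50e-3, f=0.0)
        res = fit_ivim_segmented(generate_curve(p, protocol))
        assert res.params.f == pytest.approx(0.0, abs=1e-9)
        assert res.params.D == pytest.approx(1.1e-3, rel=1e-9)

    def test_degenerate_equal_compartments_does_not_crash(self, protocol):
        p = IvimParameters(D=1.0e-3, D_star=1.0e-3, f=0.4)
        res = fit_ivim_segmented(generate_curve(p, protocol))
        assert res.converged
        # whole curve is monoexponential: D recovered, f unidentifiable (~0)
        assert res.params.D == pytest.approx(1.0e-3, rel=1e-6)
        assert res.params.f == pytest.approx(0.0, abs=1e-6)

    def test_paper_order_agrees_on_noise_free_curve(self, control_dwi_curve, control_params):
        res = fit_ivim_segmented(control_dwi_curve, FitConfig(order="low_b_first"))
        assert res.params.D == pytest.approx(control_params.D, rel=1e-3)
        assert res.params.f == pytest.approx(control_params.f, rel=0.05)
        assert res.params.D_star == pytest.approx(control_params.D_star, rel=0.05)

    def test_point_order_invariance(self, control_dwi_curve, rng):
        perm = rng.permutation(len(control_dwi_curve))
        shuffled = SignalCurve(
            tuple(np.asarray(control_dwi_curve.abscissa)[perm]),
            tuple(np.asarray(control_dwi_curve.intensities)[perm]),
            "diffusion",
        )
        a = fit_ivim_segmented(control_dwi_curve)
        b = fit_ivim_segmented(shuffled)
        assert a.params == b.params

    def test_f_clipped_and_flagged(self, protocol):
        # raised high-b tail pushes the extrapolated intercept above SI(0)
        b = np.asarray(protocol.b_values, dtype=float)
        y = np.where(b >= 200, 1.2, 1.0 * np.exp(-b * 1e-4))
        res = fit_ivim_segmented(SignalCurve(tuple(b), tuple(y), "diffusion"))
        assert res.params.f == 0.0
        assert res.bounds_hit["f"] and "f_clipped" in res.flags

    def test_missing_b0_raises(self, protocol, control_params):
        curve = generate_curve(control_params, protocol)
        trimmed = SignalCurve(curve.abscissa[1:], curve.intensities[1:], "diffusion")
        with pytest.raises(FitError):
            fit_ivim_segmented(trimmed)

    @given(
        d=st.floats(0.3e-3, 2e-3),
        d_star=st.floats(50e-3, 0.3),
        f=st.floats(0.05, 0.6),
    )
    @settings(deadline=None, max_examples=30)
    def test_noise_free_recovery_in_physiological_regime(self, d, d_star, f, protocol):
        """Perfusion decays out by b=200 when D* >~ 50e-3, so recovery is near-exact."""
        p = IvimParameters(D=d, D_star=d_star, f=f)
        res = fit_ivim_segmented(generate_curve(p, protocol))
        assert res.params.D == pytest.approx(d, rel=1e-3)
        assert res.params.f == pytest.approx(f, rel=1e-3)
        assert res.params.D_star == pytest.approx(d_star, rel=1e-2)

    def test_d_star_matches_grid_search_oracle(self, protocol, rng):
        """Bounded 1-D optimizer lands within one grid step of an exhaustive search."""
        cfg = FitConfig()
        b = np.asarray(protocol.b_values, dtype=float)
        low = b < cfg.b_split
        grid = np.arange(cfg.d_star_bounds[0], cfg.d_star_bounds[1] + 1e-4, 1e-4)
        for _ in range(20):
            p = IvimParameters(
                D=rng.uniform(0.4e-3, 1.5e-3),
                D_star=rng.uniform(20e-3, 0.2),
                f=rng.uniform(0.1, 0.5),
            )
            curve = generate_curve(p, protocol)
            res = fit_ivim_segmented(curve, cfg)
            y_low = curve.y[low]
            tissue = (1 - res.params.f) * np.exp(-b[low] * res.params.D)
            perfusion = res.params.f * np.exp(-np.outer(grid, b[low]))
            pred = protocol.SI0 * (tissue[None, :] + perfusion)
            sse = ((y_low - pred) ** 2).sum(axis=1)
            d_star_grid = grid[int(np.argmin(sse))]
            assert abs(res.params.D_star - d_star_grid) <= 1e-4 + 1e-12

    def test_snr_monotone_error_decay(self, protocol, control_params, rng):
        """Median |error| of each IVIM estimate shrinks as SNR grows."""
        snrs = [25, 50, 100, 400]
        med_err = {"D": [], "f": [], "D_star": []}
        clean = generate_curve(control_params, protocol)
        for snr in snrs:
            errs = {k: [] for k in med_err}
            for _ in range(80):
                noisy = add_rician_noise(clean, protocol.SI0 / snr, seed=rng)
                res = fit_ivim_segmented(noisy)
                errs["D"].append(abs(res.params.D - control_params.D))
                errs["f"].append(abs(res.params.f - control_params.f))
                errs["D_star"].append(abs(res.params.D_star - control_params.D_star))
            for k in med_err:
                med_err[k].append(float(np.median(errs[k])))
        for k, seq in med_err.items():
            assert all(a > b for a, b in zip(seq, seq[1:])), (k, seq)


class TestR2StarFit:
    def test_exact_recovery_on_default_echoes(self, control_gre_curve):
        res = fit_r2star(control_gre_curve)
        assert res.params.R2_star == pytest.approx(CONTROL_R2STAR, abs=1e-9)

    def test_constant_signal_zero_rate(self):
        curve = SignalCurve((3.4, 50.0, 92.1), (7.0, 7.0, 7.0), "relaxometry")
        assert fit_r2star(curve).params.R2_star == pytest.approx(0.0, abs=1e-12)

    def test_two_point_line(self):
        te = np.array([3.4, 92.1])
        y = 1000.0 * np.exp(-CONTROL_R2STAR * te * 1e-3)
        res = fit_r2star(SignalCurve(tuple(te), tuple(y), "relaxometry"))
        assert res.params.R2_star == pytest.approx(CONTROL_R2STAR, rel=1e-12)

    def test_negative_rate_clipped(self):
        curve = SignalCurve((3.4, 50.0, 92.1), (1.0, 1.5, 2.0), "relaxometry")
        res = fit_r2star(curve)
        assert res.params.R2_star == 0.0
        assert "negative_rate_clipped" in res.flags

    def test_all_nonpositive_raises(self):
        curve = SignalCurve((3.4, 9.3, 15.2), (0.0, 0.0, 0.0), "relaxometry")
        with pytest.raises(FitError):
            fit_r2star(curve)

    def test_snr_monotone_error_decay(self, protocol, control_gre_curve, rng):
        med = []
        for snr in [25, 50, 100, 400]:
            errs = []
            for _ in range(80):
                noisy = add_rician_noise(control_gre_curve, protocol.SI0 / snr, seed=rng)
                errs.append(abs(fit_r2star(noisy).params.R2_star - CONTROL_R2STAR))
            med.append(float(np.median(errs)))
        assert all(a > b for a, b in zip(med, med[1:])), med
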