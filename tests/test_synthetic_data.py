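import numpy as np
import pytest

from confmodel.binding_kinetics import BindingParams, fit_exponential_phases
from confmodel.scheme_core import SchemeValidationError
from confmodel.synthetic_data import (
    PRESETS,
    NoiseModel,
    gen_nmr_peaks,
    gen_ph_jump,
    gen_progress_curves,
    gen_stopped_flow,
    nmr_peaks_from_preset,
    ph_jump_from_preset,
    stopped_flow_from_preset,
)


class TestPresets:
    def test_printed_k2_values(self):
        assert PRESETS["HG3"].binding.K2 == pytest.approx(276e-6)
        assert PRESETS["HG3.7"].binding.K2 == pytest.approx(16.5e-6)
        assert PRESETS["HG3.17"].binding.K2 == pytest.approx(4.4e-6)

    def test_inactive_populations(self):
        assert PRESETS["HG3"].p_inactive_25C == 0.25
        assert PRESETS["HG3.7"].p_inactive_25C == 0.25
        assert PRESETS["HG3.17"].p_inactive_25C == 0.05
        assert PRESETS["HG3.17"].p_inactive_40C == 0.42
        assert PRESETS["HG3.7"].p_inactive_40C == 0.58

    def test_interconversion_band(self, preset):
        k_obs = preset.binding.k_ia + preset.binding.k_ai
        assert 1e-4 <= k_obs <= 1e-3

    def test_k1_matches_population(self, preset):
        p_i = preset.p_inactive_25C
        assert preset.binding.K1 == pytest.approx(p_i / (1 - p_i), rel=1e-12)

    def test_only_hg317_has_induced_fit(self):
        assert not PRESETS["HG3"].binding.has_induced_fit
        assert not PRESETS["HG3.7"].binding.has_induced_fit
        assert PRESETS["HG3.17"].binding.has_induced_fit


class TestStoppedFlow:
    def test_equal_coeffs_flat_traces(self):
        p = PRESETS["HG3"].binding
        ds = gen_stopped_flow(
            p, [1e-4], 1e-6, t_end=1e4, n_points=100,
            fluor_coeffs={"I": 1.0, "A": 1.0, "AL": 1.0},
            noise=NoiseModel(sigma=0.0), pseudo_first_order=False,
        )
        vals = ds.traces[0].values
        assert np.ptp(vals) < 1e-9 * np.abs(vals).max()

    def test_cs_slow_phase_amplitude_equals_inactive_fraction(self):
        # [L] >> K2, equal free-state coefficients: the slow phase converts
        # initially inactive enzyme, so its amplitude fraction equals p_I.
        # Binding kept slow enough that the fast phase survives the dead time.
        p = BindingParams(k_ia=7.5e-4, k_ai=2.5e-4, k_on=1e3, k_off=0.276)
        p_inactive = 0.25
        ds = gen_stopped_flow(
            p, [p.K2 * 50], 1e-7, t_end=4e4, n_points=400,
            fluor_coeffs={"I": 1.0, "A": 1.0, "AL": 0.5},
            noise=NoiseModel(sigma=0.0),
        )
        fit = fit_exponential_phases(ds.traces[0], n_phases=2, seed=0)
        amps = np.abs(fit.extra["amplitudes"])
        slow_fraction = amps[-1] / amps.sum()
        assert slow_fraction == pytest.approx(p_inactive, abs=0.02)

    def test_seed_reproducibility(self, tmp_path):
        from confmodel.io_cli import write_dataset

        d1 = stopped_flow_from_preset("HG3.7", seed=11, n_points=50)
        d2 = stopped_flow_from_preset("HG3.7", seed=11, n_points=50)
        write_dataset(d1, tmp_path / "a")
        write_dataset(d2, tmp_path / "b")
        for f in sorted((tmp_path / "a").glob("trace_*.csv")):
            assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes()

    def test_pseudo_first_order_guard(self):
        p = PRESETS["HG3"].binding
        with pytest.raises(SchemeValidationError, match="pseudo-first-order"):
            gen_stopped_flow(p, [1e-6], 5e-7, 10.0, noise=NoiseModel())

    def test_truth_not_in_traces(self):
        ds = stopped_flow_from_preset("HG3", seed=0, n_points=30)
        assert "K2" in ds.truth
        for tr in ds.traces:
            assert "K2" not in tr.meta


class TestProgressCurves:
    def test_kcat_zero_flat(self):
        mm = PRESETS["HG3"].mm
        from confmodel.progress_curves import MMExtendedParams

        dead = MMExtendedParams(**{**mm.as_dict(), "k_cat": 0.0})
        ds = gen_progress_curves(dead, [1e-4], 1e-6, 100.0, n_points=50)
        assert np.ptp(ds.traces[0].values) < 1e-12

    def test_first_order_initial_slope(self):
        # no conformational step or product inhibition, S0 << K_S:
        # initial slope = (k_cat/K_S) * E0 * S0 * eps_path
        from confmodel.progress_curves import MMExtendedParams, initial_rate

        mm = MMExtendedParams(
            k_ia=1.0, k_ai=1e-9, k1=1e6, k_minus1=1e3, k_cat=1.0,
            kp_on=1.0, kp_off=1e6, eps_path=1e4,
        )
        S0 = mm.K_S / 1000
        ds = gen_progress_curves(mm, [S0], 1e-6, t_end=7e3, n_points=6000)
        v0 = initial_rate(ds.traces[0], fraction=0.01)
        expected = mm.k_cat / mm.K_S * 1e-6 * S0
        assert v0 == pytest.approx(expected, rel=0.01)

    def test_doubling_e0_halves_t50(self):
        mm = PRESETS["HG3"].mm
        S0 = mm.K_M / 10  # first-order regime

        def t50(E0):
            ds = gen_progress_curves(mm, [S0], E0, t_end=4e4, n_points=3000)
            tr = ds.traces[0]
            conv = (tr.values - tr.values[0]) / (mm.eps_path * S0)
            return np.interp(0.5, conv, tr.times)

        assert t50(8e-7) / t50(1.6e-6) == pytest.approx(2.0, rel=0.05)

    def test_solubility_ceiling(self):
        mm = PRESETS["HG3"].mm
        with pytest.raises(SchemeValidationError, match="solubility"):
            gen_progress_curves(mm, [2e-3], 1e-6, 100.0)

    def test_incomplete_conversion_warning(self):
        mm = PRESETS["HG3"].mm
        ds = gen_progress_curves(mm, [mm.K_M / 3], 1.6e-6, t_end=100.0, n_points=50)
        assert any("conversion" in w for w in ds.provenance["warnings"])


class TestNmrPeaks:
    def test_p_zero_single_peak(self):
        ds = gen_nmr_peaks(0.0, noise=NoiseModel(sigma=0.0))
        tr = ds.traces[0]
        fi, w = tr.meta["center_inactive_hz"], tr.meta["width_inactive_hz"]
        mask = np.abs(tr.times - fi) < 3 * w
        # minor-region area negligible vs total
        minor = np.trapezoid(tr.values[mask], tr.times[mask])
        assert minor < 5e-3

    def test_equal_areas_equal_heights(self):
        ds = gen_nmr_peaks(0.5, widths=(18.0, 18.0), noise=NoiseModel(sigma=0.0))
        tr = ds.traces[0]
        fa, fi = tr.meta["center_active_hz"], tr.meta["center_inactive_hz"]
        h_a = tr.values[np.argmin(np.abs(tr.times - fa))]
        h_i = tr.values[np.argmin(np.abs(tr.times - fi))]
        assert h_a == pytest.approx(h_i, rel=1e-3)

    def test_quadrature_matches_closed_form_window_integral(self):
        # oracle: the closed-form Lorentzian window integral
        # area * (1/pi) * [arctan(2(b-f0)/w) - arctan(2(a-f0)/w)]
        from confmodel.interconversion_nmr import integrate_peak

        p_true = 0.37
        ds = gen_nmr_peaks(p_true, noise=NoiseModel(sigma=0.0))
        tr = ds.traces[0]
        fa, fi = tr.meta["center_active_hz"], tr.meta["center_inactive_hz"]
        w = tr.meta["width_active_hz"]

        def lorentz_window(area, f0, a, b):
            return area / np.pi * (np.arctan(2 * (b - f0) / w) - np.arctan(2 * (a - f0) / w))

        for center, own_area in [(fa, 1 - p_true), (fi, p_true)]:
            a, b = center - 10 * w, center + 10 * w
            expected = lorentz_window(1 - p_true, fa, a, b) + lorentz_window(p_true, fi, a, b)
            got = integrate_peak(tr, (a, b), baseline=0.0)
            assert got == pytest.approx(expected, rel=1e-3)

        # fat Lorentzian tails put ~0.4% of each peak in the other's window,
        # so plain window ratios recover p to ~1e-3 absolute, not exactly
        va = integrate_peak(tr, (fa - 10 * w, fa + 10 * w), baseline=0.0)
        vi = integrate_peak(tr, (fi - 10 * w, fi + 10 * w), baseline=0.0)
        assert vi / (va + vi) == pytest.approx(p_true, abs=2e-3)

    def test_fast_exchange_rejected(self):
        with pytest.raises(SchemeValidationError, match="slow exchange"):
            gen_nmr_peaks(0.3, centers=(8.30, 8.295), widths=(18.0, 18.0))


class TestPhJump:
    def test_start_at_equilibrium_flat(self):
        k_ia, k_ai = 7.5e-4, 2.5e-4
        ds = gen_ph_jump(k_ia, k_ai, p_start=0.75, t_end=3e4, noise=NoiseModel(sigma=0.0))
        assert np.ptp(ds.traces[0].values) < 1e-12

    def test_rate_is_sum_of_constants(self):
        from confmodel.interconversion_nmr import RelaxationSeries, fit_relaxation

        ds = gen_ph_jump(7.5e-4, 2.5e-4, p_start=0.3, t_end=6e3, n_points=100,
                         noise=NoiseModel(sigma=0.0))
        fit = fit_relaxation(RelaxationSeries.from_timeseries(ds.traces[0]))
        assert fit.params["k_obs"] == pytest.approx(1e-3, rel=1e-4)

    def test_activity_proportional_to_p_active(self):
        k_ia, k_ai = 6e-4, 4e-4
        ds = gen_ph_jump(k_ia, k_ai, p_start=0.2, t_end=2e4, n_points=40,
                         observable="activity", noise=NoiseModel(sigma=0.0))
        t = ds.traces[0].times
        p_eq = k_ia / (k_ia + k_ai)
        expected = p_eq + (0.2 - p_eq) * np.exp(-(k_ia + k_ai) * t)
        assert ds.traces[0].values == pytest.approx(expected, rel=1e-10)

    def test_too_short_series_rejected(self):
        with pytest.raises(SchemeValidationError, match="relaxation times"):
            gen_ph_jump(1e-3, 1e-3, 0.3, t_end=100.0)


class TestNoiseRealism:
    def test_residual_sd_matches_sigma(self):
        # residuals of the truth model vs noisy data: zero-mean, sd within
        # 10% of the requested sigma (n >= 500)
        sigma = 0.01
        ds = gen_ph_jump(7.5e-4, 2.5e-4, 0.3, t_end=6e3, n_points=600,
                         noise=NoiseModel(sigma=sigma, seed=5))
        t = ds.traces[0].times
        p_eq = 0.75
        model = p_eq + (0.3 - p_eq) * np.exp(-1e-3 * t)
        resid = ds.traces[0].values - model
        assert abs(resid.mean()) < 3 * sigma / np.sqrt(len(t))
        assert np.std(resid) == pytest.approx(sigma, rel=0.1)

    def test_preset_noise_recorded(self):
        ds = nmr_peaks_from_preset("HG3", seed=3)
        assert ds.provenance["noise_sigma"] > 0
        assert ds.provenance["preset"] == "HG3"
        ds2 = ph_jump_from_preset("HG3.17", seed=3)
        assert ds2.provenance["preset"] == "HG3.17"
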