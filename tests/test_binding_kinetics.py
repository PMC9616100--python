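import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from confmodel.binding_kinetics import (
    BindingParams,
    KobsSeries,
    binding_scheme,
    classify_mechanism,
    fit_exponential_phases,
    global_fit_binding,
    macroscopic_kd,
    predict_kobs_curve,
    simulate_binding,
    titration_midpoint_kd,
)
from confmodel.scheme_core import SchemeValidationError, TimeSeries
from confmodel.synthetic_data import PRESETS, NoiseModel, gen_stopped_flow


class TestBindingParams:
    def test_derived_constants(self):
        p = BindingParams(k_ia=7.5e-4, k_ai=2.5e-4, k_on=1e6, k_off=276.0)
        assert p.K1 == pytest.approx(1.0 / 3.0)
        assert p.K2 == pytest.approx(276e-6)
        assert p.K3 is None
        assert p.p_active == pytest.approx(0.75)

    def test_induced_fit_rates_together(self):
        with pytest.raises(SchemeValidationError, match="together"):
            BindingParams(k_ia=1e-3, k_ai=1e-3, k_on=1e6, k_off=1.0, k_if=1.0)

    def test_positive_rates_required(self):
        with pytest.raises(SchemeValidationError):
            BindingParams(k_ia=0.0, k_ai=1e-3, k_on=1e6, k_off=1.0)


class TestSimulateBinding:
    def test_reduces_to_pseudo_first_order(self):
        # k_ia >> everything, K1 -> 0: plain 1:1 binding; [AL](t) follows
        # the closed-form 1 - exp(-(k_on L + k_off) t) within 0.5%
        p = BindingParams(k_ia=1e4, k_ai=1e-4, k_on=1e6, k_off=10.0)
        L, E0 = 1e-4, 1e-8  # L = 10^4 E0
        kobs = p.k_on * L + p.k_off
        t = np.linspace(1e-4, 6.0 / kobs, 200)
        traj = simulate_binding(p, L, E0, t)
        al_inf = E0 * L / (L + p.K2)
        expected = al_inf * (1.0 - np.exp(-kobs * t))
        assert np.max(np.abs(traj["AL"].values - expected)) < 5e-3 * al_inf

    def test_zero_ligand_two_state_relaxation(self):
        p = PRESETS["HG3"].binding
        t = np.linspace(0.0, 3e4, 100)
        traj = simulate_binding(p, 0.0, 1e-6, t, p_active_init=0.5)
        assert np.all(traj["AL"].values == pytest.approx(0.0, abs=1e-18))
        k_sum = p.k_ia + p.k_ai
        dev = traj["I"].values - 1e-6 * (1 - p.p_active)
        slope = np.polyfit(t[:-1], np.log(np.abs(dev[:-1])), 1)[0]
        assert -slope == pytest.approx(k_sum, rel=1e-2)

    def test_detailed_balance_at_equilibrium(self):
        p = BindingParams(k_ia=1e-3, k_ai=5e-4, k_on=1e5, k_off=5.0,
                          k_if=0.5, k_ir=1.5)
        L, E0 = 2e-4, 1e-7
        t = np.array([0.0, 1e4, 1e5])
        traj = simulate_binding(p, L, E0, t)
        I, A = traj["I"].values[-1], traj["A"].values[-1]
        Lf, AL, ALs = traj["L"].values[-1], traj["AL"].values[-1], traj["ALs"].values[-1]
        assert I / A == pytest.approx(p.K1, rel=1e-5)
        assert A * Lf / AL == pytest.approx(p.K2, rel=1e-5)
        assert AL / ALs == pytest.approx(p.K3, rel=1e-5)


class TestFitExponentialPhases:
    def test_single_exponential_recovery(self, rng):
        t = np.linspace(0.0, 1.5, 150)
        y = 2.0 + 1.0 * np.exp(-5.0 * t)
        y_noisy = y + rng.normal(0, 0.01, t.shape)
        fit = fit_exponential_phases(TimeSeries(times=t, values=y_noisy), 1)
        assert fit.params["k1"] == pytest.approx(5.0, abs=0.1)

    def test_flat_trace_degenerate(self):
        t = np.linspace(0.0, 1.0, 50)
        fit = fit_exponential_phases(TimeSeries(times=t, values=np.ones(50)), 1)
        assert "degenerate" in fit.flags

    def test_well_separated_phases_recovered(self):
        # phases at 100 /s and 1e-3 /s, both within 5%
        t = np.geomspace(1e-4, 5e3, 400)
        y = 0.5 + 1.0 * np.exp(-100.0 * t) + 0.8 * np.exp(-1e-3 * t)
        fit = fit_exponential_phases(TimeSeries(times=t, values=y), 2)
        rates = fit.extra["rates"]
        assert rates[0] == pytest.approx(100.0, rel=0.05)
        assert rates[1] == pytest.approx(1e-3, rel=0.05)

    def test_close_rates_flagged_unresolved(self):
        t = np.linspace(0.0, 3.0, 120)
        y = np.exp(-1.0 * t) + np.exp(-2.0 * t)
        fit = fit_exponential_phases(TimeSeries(times=t, values=y), 2)
        assert "unresolved-phases" in fit.flags

    def test_too_few_points_rejected(self):
        t = np.linspace(0.0, 1.0, 12)
        with pytest.raises(SchemeValidationError, match="points"):
            fit_exponential_phases(TimeSeries(times=t, values=np.exp(-t)), 2)


class TestKobsCurves:
    def test_cs_limits(self):
        p = PRESETS["HG3"].binding
        ks = predict_kobs_curve(p, [1e-12, 1e3], "CS")
        assert ks.slow_phase[0] == pytest.approx(p.k_ia + p.k_ai, rel=1e-6)
        assert ks.slow_phase[1] == pytest.approx(p.k_ia, rel=1e-3)

    def test_if_increasing(self):
        p = PRESETS["HG3.17"].binding
        L = np.geomspace(1e-7, 1e-3, 12)
        ks = predict_kobs_curve(p, L, "IF")
        assert np.all(np.diff(ks.slow_phase) > 0)
        assert ks.slow_phase[0] == pytest.approx(p.k_ir, rel=0.05)

    def test_closed_form_matches_ode_slow_phase(self):
        # CS closed form vs full ODE + phase fitting, rate separation >= 100x
        p = BindingParams(k_ia=7.5e-4, k_ai=2.5e-4, k_on=1e6, k_off=276.0)
        for L in [100e-6, 276e-6, 1000e-6]:
            kobs_cf = predict_kobs_curve(p, [L], "CS").slow_phase[0]
            t = np.geomspace(1e-5, 8.0 / kobs_cf, 500)
            traj = simulate_binding(p, L, 1e-8, t)
            sig = traj["AL"].values
            fit = fit_exponential_phases(TimeSeries(times=t, values=sig), 2)
            assert fit.extra["rates"][-1] == pytest.approx(kobs_cf, rel=0.05)

    @settings(max_examples=20, deadline=None)
    @given(
        k_ia=st.floats(1e-4, 1e-2), k_ai=st.floats(1e-4, 1e-2),
        k_on=st.floats(1e4, 1e7), k_off=st.floats(0.1, 1e3),
    )
    def test_cs_slow_phase_monotone_nonincreasing(self, k_ia, k_ai, k_on, k_off):
        p = BindingParams(k_ia=k_ia, k_ai=k_ai, k_on=k_on, k_off=k_off)
        L = np.geomspace(p.K2 / 100, p.K2 * 100, 25)
        ks = predict_kobs_curve(p, L, "CS")
        assert np.all(np.diff(ks.slow_phase) <= 1e-18)


class TestClassifyMechanism:
    def test_cs_dataset(self):
        p = PRESETS["HG3"].binding
        L = np.geomspace(p.K2 / 4, p.K2 * 8, 6)
        assert classify_mechanism(predict_kobs_curve(p, L, "CS")) == "conformational-selection"

    def test_if_dataset(self):
        p = PRESETS["HG3.17"].binding
        L = np.geomspace(p.K2 / 4, p.K2 * 8, 6)
        assert classify_mechanism(predict_kobs_curve(p, L, "IF")) == "induced-fit"

    def test_noise_dominated_flat_is_ambiguous(self, rng):
        L = np.geomspace(1e-6, 1e-4, 8)
        kobs = 1e-3 * (1.0 + rng.normal(0, 0.01, L.shape))
        assert classify_mechanism(KobsSeries(L, kobs[:, None])) == "ambiguous"

    def test_requires_concentration_range(self):
        with pytest.raises(SchemeValidationError):
            classify_mechanism(KobsSeries(np.array([1e-6, 2e-6, 3e-6, 4e-6]),
                                          np.ones((4, 1))))


class TestGlobalFit:
    def test_noiseless_cs_recovers_truth(self):
        p = PRESETS["HG3.7"].binding
        preset = PRESETS["HG3.7"]
        ds = gen_stopped_flow(
            p, preset.ligand_concs, preset.E0_binding, 6.0 / (p.k_ia + p.k_ai),
            n_points=150, fluor_coeffs=preset.fluor_coeffs, noise=NoiseModel(sigma=0.0),
        )
        fit = global_fit_binding(
            ds.traces, scheme="CS", fixed={"k_ia": p.k_ia, "k_ai": p.k_ai},
            n_starts=4, seed=0,
        )
        assert fit.params["k_on"] == pytest.approx(p.k_on, rel=1e-3)
        assert fit.params["k_off"] == pytest.approx(p.k_off, rel=1e-3)
        assert fit.extra["derived"]["K2"] == pytest.approx(p.K2, rel=1e-3)

    def test_wrong_fixed_interconversion_degrades_fit(self):
        p = PRESETS["HG3.7"].binding
        preset = PRESETS["HG3.7"]
        ds = gen_stopped_flow(
            p, preset.ligand_concs, preset.E0_binding, 6.0 / (p.k_ia + p.k_ai),
            n_points=150, fluor_coeffs=preset.fluor_coeffs,
            noise=NoiseModel(sigma=1e-4, seed=2),
        )
        good = global_fit_binding(ds.traces, "CS",
                                  fixed={"k_ia": p.k_ia, "k_ai": p.k_ai},
                                  n_starts=4, seed=0)
        bad = global_fit_binding(ds.traces, "CS",
                                 fixed={"k_ia": p.k_ia * 5, "k_ai": p.k_ai / 5},
                                 n_starts=4, seed=0)
        assert bad.rmsd >= 2.0 * good.rmsd

    def test_needs_four_concentrations(self):
        p = PRESETS["HG3"].binding
        ds = gen_stopped_flow(p, [1e-4, 2e-4], 1e-6, 100.0, n_points=60,
                              noise=NoiseModel(), pseudo_first_order=False)
        with pytest.raises(SchemeValidationError, match="4 distinct"):
            global_fit_binding(ds.traces)

    def test_k2_recovery_distribution(self):
        # >= 20 seeded noisy datasets: median relative K2 error < 5%,
        # no systematic bias > 2% (run at reduced trace resolution for speed)
        preset = PRESETS["HG3.7"]
        p = preset.binding
        errors = []
        for seed in range(20):
            ds = gen_stopped_flow(
                p, preset.ligand_concs, preset.E0_binding, 6.0 / (p.k_ia + p.k_ai),
                n_points=120, fluor_coeffs=preset.fluor_coeffs,
                noise=NoiseModel(sigma=7e-3, seed=seed),  # ~1% of signal range
            )
            fit = global_fit_binding(
                ds.traces, "CS", fixed={"k_ia": p.k_ia, "k_ai": p.k_ai},
                n_starts=4, seed=seed,
            )
            errors.append(fit.extra["derived"]["K2"] / p.K2 - 1.0)
        errors = np.array(errors)
        assert np.median(np.abs(errors)) < 0.05
        assert abs(np.median(errors)) < 0.02


class TestMacroscopicKd:
    def test_k1_zero_equals_k2(self):
        p = BindingParams(k_ia=1e4, k_ai=1e-6, k_on=1e6, k_off=10.0)
        assert macroscopic_kd(p) == pytest.approx(p.K2, rel=1e-9)

    def test_k1_one_doubles_kd(self):
        p = BindingParams(k_ia=1e-3, k_ai=1e-3, k_on=1e6, k_off=10.0)
        assert macroscopic_kd(p) == pytest.approx(2.0 * p.K2, rel=1e-12)

    def test_induced_fit_tightens_kd(self):
        base = dict(k_ia=1e-3, k_ai=1e-3, k_on=1e6, k_off=10.0)
        no_if = BindingParams(**base)
        with_if = BindingParams(**base, k_if=1.0, k_ir=1.0)
        assert macroscopic_kd(with_if) == pytest.approx(macroscopic_kd(no_if) / 2)

    def test_matches_equilibrium_titration(self, preset):
        p = preset.binding
        assert titration_midpoint_kd(p) == pytest.approx(macroscopic_kd(p), rel=5e-3)


class TestPhaseCountSelection:
    def test_bic_picks_two_phases(self):
        t = np.geomspace(1e-3, 5e3, 300)
        y = 0.5 + 1.0 * np.exp(-50.0 * t) + 0.8 * np.exp(-1e-3 * t)
        y = y + np.random.default_rng(0).normal(0, 0.002, t.shape)
        from confmodel.binding_kinetics import choose_n_phases

        assert choose_n_phases(TimeSeries(times=t, values=y)) == 2

    def test_bic_picks_one_phase(self):
        t = np.linspace(0.0, 5.0, 200)
        y = 1.0 + np.exp(-2.0 * t)
        y = y + np.random.default_rng(1).normal(0, 0.002, t.shape)
        from confmodel.binding_kinetics import choose_n_phases

        assert choose_n_phases(TimeSeries(times=t, values=y)) == 1
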