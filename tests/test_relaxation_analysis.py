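"""Temperature laws: VFT, Arrhenius, kink, fragility, coupling model."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from dielkin.relaxation_analysis import (
    GAS_CONSTANT,
    LN10,
    VFTFit,
    angell_transform,
    cm_predicted_jg_time,
    coupling_parameter,
    detect_kink,
    fit_arrhenius,
    fit_vft,
    fragility_index,
    kinetic_tg,
    summarize_relaxation_map,
    tg_tm_ratio,
)
from dielkin.spectrum_fitting import RelaxationRecord, RelaxationTable

DIA_VFT = dict(log10_tau0=-21.0, D=10.5, T0=214.0)
NOR_VFT = dict(log10_tau0=-21.0, D=10.3, T0=239.0)


def _records(temps, taus, process="alpha", **kw):
    return [RelaxationRecord(temperature=float(T), process=process,
                             tau_max=float(t), delta_eps=1.0, a=1.0, b=0.6, **kw)
            for T, t in zip(temps, taus)]


class TestFitVFT:
    def test_noise_free_round_trip_is_exact(self):
        truth = VFTFit(**DIA_VFT, convention="decadic")
        T = np.linspace(318.0, 390.0, 8)
        fit = fit_vft((T, 10.0 ** truth.log10_tau(T)), convention="decadic")
        assert fit.log10_tau0 == pytest.approx(-21.0, abs=1e-6)
        assert fit.D == pytest.approx(10.5, abs=1e-6)
        assert fit.T0 == pytest.approx(214.0, abs=1e-6)

    @pytest.mark.parametrize("params", [DIA_VFT, NOR_VFT,
                                        dict(log10_tau0=-20.7, D=11.0, T0=207.0)])
    def test_all_material_parameter_sets_recover_exactly(self, params):
        truth = VFTFit(**params, convention="decadic")
        T = np.linspace(truth.T0 + 95.0, truth.T0 + 170.0, 9)
        fit = fit_vft((T, 10.0 ** truth.log10_tau(T)), convention="decadic")
        for name in ("log10_tau0", "D", "T0"):
            assert getattr(fit, name) == pytest.approx(params[name], rel=1e-6, abs=1e-5)

    def test_arrhenius_data_drives_t0_to_zero(self):
        # T0 -> 0 limit: D*T0 (decadic) approaches Ea/(R ln10)
        ea = 50e3
        T = np.linspace(150.0, 250.0, 8)
        tau = 10.0 ** (-14.0 + ea / (GAS_CONSTANT * LN10 * T))
        fit = fit_vft((T, tau), convention="decadic")
        assert fit.T0 < 10.0
        assert fit.D * fit.T0 == pytest.approx(ea / (GAS_CONSTANT * LN10), rel=0.02)

    def test_noisy_table_recovers_fragility_strength(self):
        truth = VFTFit(**DIA_VFT, convention="decadic")
        T = np.linspace(317.6, 392.6, 15)
        rng = np.random.default_rng(3)
        tau = 10.0 ** truth.log10_tau(T) * np.exp(rng.normal(0.0, 0.01, T.size))
        fit = fit_vft((T, tau), convention="decadic")
        assert fit.D == pytest.approx(10.5, abs=0.6)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_vft((np.array([320.0, 330.0, 340.0]), np.array([1.0, 0.1, 0.01])))


class TestKineticTg:
    def test_dia_parameters_decadic(self):
        fit = VFTFit(**DIA_VFT, convention="decadic")
        assert kinetic_tg(fit) == pytest.approx(312.6, abs=1.0)

    def test_nor_parameters_decadic_cross_checked_by_bisection(self):
        fit = VFTFit(**NOR_VFT, convention="decadic")
        tg = kinetic_tg(fit)
        assert tg == pytest.approx(346.0, abs=0.5)
        lo, hi = fit.T0 + 1.0, 500.0
        for _ in range(100):
            mid = 0.5 * (lo + hi)
            if fit.log10_tau(mid) > 2.0:
                lo = mid
            else:
                hi = mid
        assert tg == pytest.approx(0.5 * (lo + hi), abs=1e-9)

    def test_constructed_identity_tg_equals_twice_t0(self):
        # D*T0/(T-T0) = 16 at T = 2*T0 with log10 tau0 = -14
        fit = VFTFit(log10_tau0=-14.0, D=16.0, T0=150.0, convention="decadic")
        assert kinetic_tg(fit) == pytest.approx(300.0, rel=1e-12)


class TestFragility:
    def test_dia_natural_convention_matches_reported_value(self):
        fit = VFTFit(**DIA_VFT, convention="natural")
        assert fragility_index(fit, tg=312.6) == pytest.approx(31.4, abs=0.1)

    def test_arrhenius_minimal_fragility(self):
        # pure Arrhenius from tau0 = 1e-16 s to 100 s at Tg: m_p = 18
        tg, log10_tau0 = 300.0, -16.0
        ea = (2.0 - log10_tau0) * GAS_CONSTANT * LN10 * tg
        T = np.linspace(250.0, 400.0, 10)
        tau = 10.0 ** (log10_tau0 + ea / (GAS_CONSTANT * LN10 * T))
        fit = fit_vft((T, tau), convention="decadic")
        assert fragility_index(fit, tg=tg) == pytest.approx(18.0, rel=0.01)

    @pytest.mark.parametrize("convention", ["natural", "decadic"])
    def test_matches_central_difference_of_fitted_curve(self, convention):
        fit = VFTFit(**DIA_VFT, convention=convention)
        tg = kinetic_tg(fit)
        h = 0.01
        # derivative of log10 tau wrt (tg/T) at T = tg via central difference
        x = tg / np.array([tg / (1 - h / 2), tg / (1 + h / 2)])
        y = fit.log10_tau(tg / x)
        slope = (y[1] - y[0]) / (x[1] - x[0])
        assert fragility_index(fit, tg) == pytest.approx(slope, rel=1e-3)

    def test_domain_error_below_t0(self):
        fit = VFTFit(**DIA_VFT, convention="natural")
        with pytest.raises(ValueError):
            fragility_index(fit, tg=200.0)


def test_vft_convention_conversion_invariance():
    dec = VFTFit(**DIA_VFT, convention="decadic")
    nat = dec.to_convention("natural")
    assert nat.D == pytest.approx(10.5 * LN10)
    T = np.linspace(320.0, 400.0, 30)
    assert np.max(np.abs(dec.log10_tau(T) - nat.log10_tau(T))) < 1e-12
    assert kinetic_tg(dec) == pytest.approx(kinetic_tg(nat), rel=1e-12)
    assert fragility_index(dec) == pytest.approx(fragility_index(nat), rel=1e-12)
    assert nat.to_convention("decadic").D == pytest.approx(dec.D, rel=1e-12)


class TestArrhenius:
    def test_collinear_points_recover_slope_exactly(self):
        ea = 40e3
        T = np.array([100.0, 150.0, 300.0])
        tau = np.exp(-30.0 + ea / (GAS_CONSTANT * T))
        fit = fit_arrhenius((T, tau))
        assert fit.ea_kj_mol == pytest.approx(40.0, rel=1e-10)
        assert fit.log10_tau_inf == pytest.approx(-30.0 / LN10, rel=1e-10)

    def test_gamma_like_data_with_noise(self):
        T = np.linspace(150.0, 250.0, 12)
        rng = np.random.default_rng(11)
        tau = 10.0 ** (-14.0 + 35e3 / (GAS_CONSTANT * LN10 * T)) * np.exp(rng.normal(0, 0.02, T.size))
        fit = fit_arrhenius((T, tau))
        assert fit.ea_kj_mol == pytest.approx(35.0, abs=2.0)

    def test_subrange_fit_beats_full_range_across_kink(self, dia_card):
        T = np.arange(272.0, 353.0, 5.0)
        tau = np.array([dia_card.tau_max("beta", t) for t in T])
        full = fit_arrhenius((T, tau))
        below = fit_arrhenius((T, tau), t_range=(0.0, dia_card.t_g))
        def ssr(fit, Ts, ts):
            return np.sum((fit.log10_tau(Ts) - np.log10(ts)) ** 2)
        mask = T <= dia_card.t_g
        assert ssr(below, T[mask], tau[mask]) < 0.1 * ssr(full, T, tau)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            fit_arrhenius((np.array([100.0, 200.0]), np.array([1.0, 0.1])))


class TestDetectKink:
    def test_finds_generator_kink_at_tg(self, dia_card):
        T = np.arange(282.0, 343.0, 4.0)
        tau = np.array([dia_card.tau_max("beta", t) for t in T])
        kink = detect_kink((T, tau))
        assert kink.t_break == pytest.approx(dia_card.t_g, abs=5.0)
        assert kink.ea_below == pytest.approx(55.0, abs=1.0)
        assert kink.ea_above > kink.ea_below

    def test_single_slope_data_gives_equal_activation_energies(self):
        T = np.linspace(250.0, 350.0, 12)
        rng = np.random.default_rng(4)
        tau = 10.0 ** (-13.0 + 45e3 / (GAS_CONSTANT * LN10 * T)) * np.exp(rng.normal(0, 0.01, T.size))
        kink = detect_kink((T, tau))
        joint = 2 * math.hypot(kink.fit_below.stderr["ea_kj_mol"],
                               kink.fit_above.stderr["ea_kj_mol"])
        assert abs(kink.ea_below - kink.ea_above) < max(joint, 2.0)

    def test_requires_points_on_both_sides(self):
        T = np.linspace(250.0, 300.0, 8)
        tau = 10.0 ** (-13.0 + 45e3 / (GAS_CONSTANT * LN10 * T))
        with pytest.raises(ValueError):
            detect_kink((T, tau), tg=350.0)

    def test_beta_traces_superpose_in_reduced_temperature(self):
        # two materials built from one reduced-temperature law must overlap
        def reduced_law(tg, T):
            return -6.0 + 8.0 * (tg / T)  # log10 tau as function of Tg/T
        out = {}
        for tg in (312.6, 347.2):
            x = np.linspace(0.85, 1.15, 13)
            T = tg / x
            out[tg] = (x, reduced_law(tg, T))
        x = np.linspace(0.88, 1.12, 25)
        y1 = np.interp(x, *out[312.6])
        y2 = np.interp(x, *out[347.2])
        assert np.max(np.abs(y1 - y2)) < 0.2


class TestCouplingModel:
    def test_debye_limit_no_coupling(self):
        assert coupling_parameter(1.0, 1.0) == 0.0

    @pytest.mark.parametrize("b,expected", [(0.59, 0.349), (0.50, 0.431)])
    def test_cole_davidson_values(self, b, expected):
        n = coupling_parameter(1.0, b)
        assert n == pytest.approx(expected, abs=5e-4)
        # independent log-exp evaluation
        assert n == pytest.approx(1.0 - math.exp(math.log(b) / 1.23), rel=1e-12)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            coupling_parameter(0.0, 0.5)

    def test_limits_and_value(self):
        assert cm_predicted_jg_time(0.37, 0.0) == pytest.approx(0.37)
        assert cm_predicted_jg_time(0.37, 1.0) == pytest.approx(2e-12)
        assert cm_predicted_jg_time(100.0, 0.349) == pytest.approx(1.66e-3, rel=5e-3)

    @given(st.floats(1e-6, 1e4), st.floats(1e-6, 1e4))
    def test_monotone_in_tau_alpha(self, t1, t2):
        lo, hi = sorted((t1, t2))
        assert cm_predicted_jg_time(lo, 0.4) <= cm_predicted_jg_time(hi, 0.4) * (1 + 1e-12)

    @given(st.floats(0.05, 0.95), st.floats(0.05, 0.95))
    def test_monotone_decreasing_in_coupling_for_slow_alpha(self, n1, n2):
        lo, hi = sorted((n1, n2))
        assert cm_predicted_jg_time(100.0, hi) <= cm_predicted_jg_time(100.0, lo) * (1 + 1e-12)


class TestAngell:
    def test_alpha_passes_through_unity_and_two(self):
        fit = VFTFit(**DIA_VFT, convention="decadic")
        tg = kinetic_tg(fit)
        recs = _records([tg], [10.0 ** fit.log10_tau(tg)])
        df = angell_transform(recs, tg)
        assert df["tg_over_t"].iloc[0] == pytest.approx(1.0)
        assert df["log10_tau"].iloc[0] == pytest.approx(2.0, abs=1e-9)

    def test_same_d_and_tau0_superpose_in_reduced_coordinates(self):
        # VFT depends only on T/T0 for fixed D, so curves with different
        # T0 coincide when plotted against Tg/T
        curves = {}
        for T0 in (214.0, 239.0):
            fit = VFTFit(log10_tau0=-21.0, D=10.5, T0=T0, convention="decadic")
            tg = kinetic_tg(fit)
            x = np.linspace(0.8, 1.0, 21)
            curves[T0] = fit.log10_tau(tg / x)
        assert np.max(np.abs(curves[214.0] - curves[239.0])) < 1e-9

    def test_gamma_processes_do_not_superpose(self, dia_card, nor_card):
        x = np.array([1.2])
        vals = {}
        for card in (dia_card, nor_card):
            T = card.t_g / x
            vals[card.name] = card.log10_tau("gamma", float(T[0]))
        assert abs(vals["dia_like"] - vals["nor_like"]) > 1.0


class TestTgTmRatio:
    @pytest.mark.parametrize("tg,tm,expected", [
        (317.8, 404.0, 0.78),
        (346.8, 487.0, 0.71),
        (313.0, 415.6, 0.75),
    ])
    def test_reported_ratios(self, tg, tm, expected):
        assert tg_tm_ratio(tg, tm).reported == pytest.approx(expected, abs=1e-12)

    def test_equal_temperatures_warn_but_return(self):
        with pytest.warns(UserWarning):
            r = tg_tm_ratio(300.0, 300.0)
        assert r.reported == 1.0
        assert r.warning


def test_summarize_relaxation_map_states_convention(dia_card):
    truth = VFTFit(**DIA_VFT, convention="decadic")
    T = np.linspace(320.0, 370.0, 8)
    table = RelaxationTable(records=_records(T, 10.0 ** truth.log10_tau(T)))
    Tb = np.linspace(280.0, 310.0, 5)
    for t, tau in zip(Tb, (10.0 ** (-12.0 + 50e3 / (GAS_CONSTANT * LN10 * Tb)))):
        table.records.append(RelaxationRecord(temperature=float(t), process="beta",
                                              tau_max=float(tau), delta_eps=0.3,
                                              a=0.4, b=1.0))
    summary = summarize_relaxation_map(table, convention="decadic", tm=404.0)
    assert summary["convention"] == "decadic"
    assert summary["tg_kinetic_K"] == pytest.approx(312.6, abs=1.5)
    assert summary["tg_over_tm"] == pytest.approx(0.77, abs=0.011)
    assert "beta" in summary and summary["beta"]["ea_kj_mol"] == pytest.approx(50.0, rel=0.01)
    assert "coupling_model" in summary
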