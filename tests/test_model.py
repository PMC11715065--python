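"""Structural model: allometry, compartments, effect site, Emax, reversal."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import dabipkpd as dp
from dabipkpd.errors import InvalidInputError


class TestScaleParameter:
    def test_standard_weight_identity(self):
        assert dp.scale_parameter(0.0453, 70, 0.75) == pytest.approx(0.0453)

    @pytest.mark.parametrize("p_std, w, exp, expected", [
        (0.0453, 35, 0.75, 0.0453 * 0.5 ** 0.75),
        (2.94, 35, 1.0, 1.47),
        (0.268, 140, 0.75, 0.268 * 2 ** 0.75),
    ])
    def test_power_law(self, p_std, w, exp, expected):
        assert dp.scale_parameter(p_std, w, exp) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("p_std, w", [(0.0, 70), (-1.0, 70), (1.0, 0.0), (1.0, -5)])
    def test_invalid_inputs(self, p_std, w):
        with pytest.raises(InvalidInputError):
            dp.scale_parameter(p_std, w, 0.75)

    @given(w=st.floats(10, 300), exp=st.sampled_from([0.75, 1.0]))
    def test_multiplicative_in_weight_ratio(self, w, exp):
        # scaling twice through an intermediate weight equals scaling once
        via = dp.scale_parameter(1.0, w, exp)
        assert via == pytest.approx((w / 70.0) ** exp, rel=1e-12)


class TestIndividualParameters:
    def test_typical_subject_is_identity(self, pop):
        ind = dp.individual_parameters(pop, dp.Subject(id="s", weight=70))
        assert ind.pk.CL == pytest.approx(pop.pk.CL)
        assert ind.pk.V2 == pytest.approx(pop.pk.V2)
        assert ind.pd.Ce50 == pytest.approx(pop.pd.Ce50)

    def test_exponential_eta_doubles(self, pop):
        ind = dp.individual_parameters(
            pop, dp.Subject(id="s", weight=70, eta={"CL": np.log(2)}))
        assert ind.pk.CL == pytest.approx(2 * pop.pk.CL)

    def test_allometry_and_eta_combine(self, pop):
        ind = dp.individual_parameters(
            pop, dp.Subject(id="s", weight=50, eta={"CL": 0.3}))
        expected = 0.0453 * (50 / 70) ** 0.75 * np.exp(0.3)
        assert ind.pk.CL == pytest.approx(expected, rel=1e-12)

    def test_unknown_eta_key_rejected(self):
        with pytest.raises(Exception):
            dp.Subject(id="s", weight=70, eta={"CLX": 0.1})


class TestSimulatePK:
    def test_empty_regimen_all_zero(self, pop):
        sim = dp.simulate_pk(pop.pk, dp.Regimen(), np.linspace(1, 100, 20))
        for channel in (sim.C1, sim.C2, sim.Ce, sim.C_ida):
            assert np.all(channel == 0)

    def test_bolus_initial_concentration_is_dose_over_v1(self, pop):
        # 4 mg/kg x 70 kg delivered as a near-instant input
        reg = dp.Regimen().add(dp.DABIGATRAN, 0.0, 280.0, 0.0)
        sim = dp.simulate_pk(pop.pk, reg, np.array([1e-3]))
        assert sim.C1[0] == pytest.approx(280.0 / 2.94, rel=1e-3)

    def test_infusion_steady_state_is_rate_over_cl(self, pop):
        rate = 0.0453  # mg/min == CL -> 1 mg/L at steady state
        reg = dp.Regimen().add(dp.DABIGATRAN, 0.0, rate * 2e5, 2e5)
        sim = dp.simulate_pk(pop.pk, reg, np.array([1.8e5]))
        assert sim.C1[0] == pytest.approx(1.0, rel=1e-3)

    def test_non_monotone_grid_rejected(self, pop):
        with pytest.raises(InvalidInputError):
            dp.simulate_pk(pop.pk, dp.Regimen(), np.array([1.0, 1.0, 2.0]))

    def test_closed_form_matches_ode(self, pop):
        """The bi-exponential superposition path against the LSODA oracle."""
        reg = dp.study_regimen(65.0)
        times = np.array([0.5, 1, 2, 5, 15, 30, 60, 90, 120, 120.5, 121,
                          125, 135, 150, 180, 240, 360, 600, 1560.0])
        closed = dp.simulate_pk(pop.pk, reg, times, ida=pop.ida)
        ode = dp.simulate_pk(pop.pk, reg, times, ida=pop.ida, method="ode")
        for name in ("C1", "C2", "Ce", "C_ida"):
            a, b = getattr(closed, name), getattr(ode, name)
            assert np.max(np.abs(a - b)) <= 1e-3 * np.max(np.abs(b))

    def test_mass_balance(self, pop):
        reg = dp.study_regimen(70.0)
        times = np.linspace(2, 1560, 80)
        ode = dp.simulate_pk(pop.pk, reg, times, ida=pop.ida, method="ode")
        administered = 280.0  # idarucizumab does not enter the PK balance
        balance = ode.A1 + ode.A2 + ode.eliminated
        assert np.max(np.abs(balance - administered)) <= 1e-3 * administered

    @given(split=st.floats(0.05, 0.95))
    def test_split_infusion_invariance(self, pop, split):
        """Splitting one infusion into two contiguous events changes nothing."""
        total, dur = 280.0, 30.0
        times = np.array([5.0, 15.0, 40.0, 90.0])
        one = dp.Regimen().add(dp.DABIGATRAN, 0.0, total, dur)
        two = (dp.Regimen()
               .add(dp.DABIGATRAN, 0.0, total * split, dur * split)
               .add(dp.DABIGATRAN, dur * split, total * (1 - split),
                    dur * (1 - split)))
        a = dp.simulate_pk(pop.pk, one, times)
        b = dp.simulate_pk(pop.pk, two, times)
        np.testing.assert_allclose(b.C1, a.C1, rtol=1e-9, atol=1e-12)
        np.testing.assert_allclose(b.Ce, a.Ce, rtol=1e-9, atol=1e-12)


class TestEffectSite:
    def test_keo_from_half_time(self, pop):
        assert pop.pk.keo == pytest.approx(np.log(2) / 1.04, rel=1e-12)
        assert pop.pk.keo == pytest.approx(0.66651, rel=1e-4)

    def test_step_reaches_half_at_half_time(self):
        t_half = 1.04
        times = np.linspace(0, 20, 4001)
        c1 = np.full_like(times, 3.0)
        ce = dp.effect_site(times, c1, np.log(2) / t_half)
        assert np.interp(t_half, times, ce) == pytest.approx(1.5, rel=1e-3)
        assert ce[-1] == pytest.approx(3.0, rel=1e-4)  # equilibrium

    def test_invalid_keo(self):
        with pytest.raises(InvalidInputError):
            dp.effect_site([0, 1], [0, 1], 0.0)

    def test_no_overshoot_of_monotone_input(self, pop):
        """Ce never exceeds the running maximum of a monotone C1."""
        times = np.linspace(0, 30, 301)
        c1 = 5.0 * (1 - np.exp(-0.3 * times))
        ce = dp.effect_site(times, c1, pop.pk.keo)
        assert np.all(ce <= np.maximum.accumulate(c1) + 1e-12)


class TestEmaxResponse:
    def test_baseline_half_max_and_asymptote(self, pop):
        assert dp.emax_response(0.0, pop.pd) == pytest.approx(pop.pd.E0)
        assert dp.emax_response(64.2, pop.pd) == pytest.approx(pop.pd.E0 + 90.0)
        assert dp.emax_response(1e9, pop.pd) == pytest.approx(
            pop.pd.E0 + 180.0, rel=1e-6)

    def test_negative_ce_rejected(self, pop):
        with pytest.raises(InvalidInputError):
            dp.emax_response(-1.0, pop.pd)

    @given(ce=st.lists(st.floats(0, 1e3), min_size=2, max_size=10))
    def test_monotone_in_ce(self, pop, ce):
        ce = np.sort(np.asarray(ce))
        r = dp.emax_response(ce, pop.pd)
        assert np.all(np.diff(r) >= -1e-12)

    def test_log_symmetry_around_ce50(self, pop):
        """E(Ce50*k) - E0 and E(Ce50/k) - E0 sum to Emax for any k."""
        for k in (2.0, 5.0, 17.3):
            up = dp.emax_response(pop.pd.Ce50 * k, pop.pd) - pop.pd.E0
            dn = dp.emax_response(pop.pd.Ce50 / k, pop.pd) - pop.pd.E0
            assert up + dn == pytest.approx(pop.pd.Emax, rel=1e-9)


class TestIdarucizumabEffect:
    def test_no_event_is_zero(self, pop):
        reg = dp.Regimen().add(dp.DABIGATRAN, 0.0, 280.0, 1.0)
        eff = dp.idarucizumab_effect(reg, pop.ida, np.linspace(1, 600, 50))
        assert np.all(eff == 0)

    def test_monoexponential_washout(self, pop):
        reg = dp.Regimen().add(dp.IDARUCIZUMAB, 0.0, 1050.0, 0.5)
        ida = pop.ida
        t_end = ida.dur_ida
        t_half_later = t_end + np.log(2) / ida.k_ida
        times = np.array([t_end, t_half_later, 1e4])
        eff = dp.idarucizumab_effect(reg, ida, times)
        assert eff[1] == pytest.approx(0.5 * eff[0], rel=1e-9)
        assert abs(eff[2]) < 1e-8  # complete washout

    def test_effect_is_nonpositive_and_scales_with_slope(self, pop):
        reg = dp.Regimen().add(dp.IDARUCIZUMAB, 120.0, 1050.0, 0.5)
        times = np.linspace(121, 600, 100)
        eff = dp.idarucizumab_effect(reg, pop.ida, times)
        assert np.all(eff <= 0)
        stronger = dp.IdarucizumabParameters(pop.ida.k_ida, pop.ida.dur_ida,
                                             2 * pop.ida.slope_ida)
        assert np.allclose(dp.idarucizumab_effect(reg, stronger, times), 2 * eff)


class TestPredictRTime:
    def test_baseline_without_drug(self, pop):
        sim = dp.simulate_pk(pop.pk, dp.Regimen(), np.linspace(1, 50, 10))
        r = dp.predict_r_time(sim, pop.pd, pop.ida)
        np.testing.assert_allclose(r, pop.pd.E0)

    def test_additivity_of_reversal(self, pop):
        times = np.linspace(0.5, 240, 200)
        reg = dp.study_regimen(70.0)
        sim = dp.simulate_pk(pop.pk, reg, times, ida=pop.ida)
        with_rev = dp.predict_r_time(sim, pop.pd, pop.ida)
        no_rev = dp.emax_response(sim.Ce, pop.pd)
        rev = dp.idarucizumab_effect(reg, pop.ida, times)
        np.testing.assert_allclose(with_rev, np.maximum(no_rev + rev, 0.0),
                                   rtol=1e-9)

    def test_floor_at_zero(self, pop):
        strong = dp.IdarucizumabParameters(0.001, 5.0, 1e4)
        reg = dp.Regimen().add(dp.IDARUCIZUMAB, 0.0, 1000.0, 0.5)
        sim = dp.simulate_pk(dp.PKParameters(0.05, 0.3, 3, 9, 1.0), reg,
                             np.array([30.0]), ida=strong)
        r = dp.predict_r_time(sim, dp.PDParameters(6, 180, 64.2), strong)
        assert r[0] == 0.0
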