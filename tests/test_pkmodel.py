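"""Structural model: covariate equations, infusion kinetics, residual error."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from neopkpd import (
    DoseEvent,
    IndividualParams,
    PopModel,
    concentration,
    individual_params,
    make_record,
    residual_observe,
    steady_state_profile,
)

from oracles import ode_concentration


class TestCovariateModel:
    def test_reference_covariates_return_typical_values(self, model, reference_covariates):
        """At the median covariates all normalization ratios are 1."""
        p = individual_params(model, reference_covariates, (0.0, 0.0))
        assert p.cl_L_h == pytest.approx(0.503, abs=5e-4)
        assert p.v_L == pytest.approx(1.63, abs=5e-4)

    def test_half_weight_pure_allometry(self, model):
        """CW = 1340 g at reference ages: CL scales by 0.5^0.75."""
        cov = make_record(36.5, 12.0, 1300.0, 1340.0)
        p = individual_params(model, cov, (0.0, 0.0))
        assert p.cl_L_h == pytest.approx(0.503 * 0.5**0.75, rel=1e-12)
        # hand value from evaluating the power law in the log domain
        assert p.cl_L_h == pytest.approx(0.299, abs=1e-3)

    def test_zero_age_exponents_leave_only_allometry(self, reference_covariates):
        m = PopModel(1.63, 0.503, 0.0, 0.0, omega=np.zeros((2, 2)), sigma_prop=0.0)
        cov1 = make_record(30.0, 40.0, 2000.0, 2680.0)
        p1 = individual_params(m, cov1, (0.0, 0.0))
        p0 = individual_params(m, reference_covariates, (0.0, 0.0))
        assert p1.cl_L_h == pytest.approx(p0.cl_L_h, rel=1e-12)

    def test_etas_scale_lognormally(self, model, reference_covariates):
        p = individual_params(model, reference_covariates, (0.3, -0.2))
        p0 = individual_params(model, reference_covariates, (0.0, 0.0))
        assert p.cl_L_h == pytest.approx(p0.cl_L_h * np.exp(0.3), rel=1e-12)
        assert p.v_L == pytest.approx(p0.v_L * np.exp(-0.2), rel=1e-12)

    def test_nonpositive_covariate_rejected(self, model):
        with pytest.raises(ValueError):
            make_record(36.5, -1.0, 2500.0, 2680.0)


class TestConcentration:
    P = IndividualParams(cl_L_h=0.503, v_L=1.63)

    def test_zero_before_first_dose(self):
        doses = [DoseEvent(55.0, 2.0, 1.0)]
        assert concentration(0.0, doses, self.P) == 0.0
        assert concentration(1.99, doses, self.P) == 0.0

    def test_single_dose_end_of_infusion_matches_ode_oracle(self):
        doses = [DoseEvent(55.0, 0.0, 1.0)]
        t = np.array([0.5, 1.0, 2.0, 5.0, 8.0])
        closed = concentration(t, doses, self.P)
        oracle = ode_concentration(t, doses, self.P)
        np.testing.assert_allclose(closed, oracle, rtol=1e-7)
        assert closed[1] == pytest.approx(29.0, abs=0.1)

    def test_multidose_matches_ode_oracle(self):
        doses = [DoseEvent(50.0, 8.0 * k, 2.0) for k in range(4)]
        t = np.array([1.0, 7.5, 9.0, 20.0, 31.0])
        np.testing.assert_allclose(
            concentration(t, doses, self.P),
            ode_concentration(t, doses, self.P),
            rtol=1e-7,
        )

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        amounts=st.lists(st.floats(1.0, 200.0), min_size=1, max_size=5),
        scale=st.floats(0.1, 10.0),
    )
    def test_linearity_in_dose(self, amounts, scale):
        """Scaling every dose amount scales concentration everywhere."""
        doses = [DoseEvent(a, 6.0 * i, 1.0) for i, a in enumerate(amounts)]
        scaled = [DoseEvent(a * scale, 6.0 * i, 1.0) for i, a in enumerate(amounts)]
        t = np.linspace(0.0, 40.0, 23)
        np.testing.assert_allclose(
            concentration(t, scaled, self.P),
            scale * concentration(t, doses, self.P),
            rtol=1e-12, atol=1e-14,
        )

    def test_superposition_of_single_dose_curves(self):
        doses = [DoseEvent(40.0 + 10 * k, 7.0 * k, 1.5) for k in range(5)]
        t = np.linspace(0.0, 50.0, 101)
        total = concentration(t, doses, self.P)
        parts = sum(concentration(t, [d], self.P) for d in doses)
        np.testing.assert_allclose(total, parts, atol=1e-12)

    def test_monotone_decay_after_last_infusion(self):
        doses = [DoseEvent(55.0, 8.0 * k, 1.0) for k in range(3)]
        t = np.linspace(17.0 + 1e-9, 60.0, 400)
        c = concentration(t, doses, self.P)
        assert np.all(np.diff(c) < 0)

    def test_dimensional_invariance(self):
        """Scaling dose and V together leaves concentration unchanged."""
        doses = [DoseEvent(55.0, 0.0, 1.0)]
        big = [DoseEvent(110.0, 0.0, 1.0)]
        p2 = IndividualParams(cl_L_h=2 * 0.503, v_L=2 * 1.63)
        t = np.linspace(0.5, 20.0, 40)
        np.testing.assert_allclose(
            concentration(t, doses, self.P), concentration(t, big, p2), rtol=1e-12
        )


class TestSteadyState:
    P = IndividualParams(cl_L_h=0.503, v_L=1.63)

    def test_matches_30_interval_superposition(self):
        dose, tau, T = 80.4, 8.0, 1.0
        css = steady_state_profile(dose, tau, T, self.P)
        doses = [DoseEvent(dose, tau * k, T) for k in range(30)]
        t_local = np.linspace(0.0, tau - 1e-9, 200)
        sup = concentration(29 * tau + t_local, doses, self.P)
        np.testing.assert_allclose(css(t_local), sup, rtol=1e-6)

    def test_end_of_infusion_value(self):
        # 30 mg/kg at 2680 g, q8h, 1-h infusion
        css = steady_state_profile(30.0 * 2.680, 8.0, 1.0, self.P)
        assert css(1.0) == pytest.approx(46.4, abs=0.1)

    def test_no_accumulation_limit(self):
        """ke*tau large: steady state equals the single-dose profile."""
        p = IndividualParams(cl_L_h=10.0, v_L=1.0)  # ke = 10/h, tau = 8 h
        css = steady_state_profile(100.0, 8.0, 1.0, p)
        t = np.linspace(0.01, 7.99, 50)
        single = concentration(t, [DoseEvent(100.0, 0.0, 1.0)], p)
        np.testing.assert_allclose(css(t), single, rtol=1e-9)

    def test_auc_over_interval_is_dose_over_clearance(self):
        dose = 80.4
        css = steady_state_profile(dose, 8.0, 1.0, self.P)
        auc, _ = quad(css, 0.0, 8.0, limit=200)
        assert auc == pytest.approx(dose / self.P.cl_L_h, rel=1e-6)

    def test_infusion_longer_than_interval_rejected(self):
        with pytest.raises(ValueError):
            steady_state_profile(50.0, 8.0, 8.0, self.P)


class TestResidualError:
    def test_zero_sigma_is_identity(self):
        assert residual_observe(10.0, 0.0, 1.7) == 10.0

    def test_published_sigma_one_sd_draw(self):
        assert residual_observe(10.0, 0.288, 1.0) == pytest.approx(12.88)

    def test_mean_preserved_over_draws(self):
        rng = np.random.default_rng(12)
        obs = residual_observe(10.0, 0.288, rng.standard_normal(100_000))
        # CLT: SE of the mean = 10*0.288/sqrt(1e5) ~ 0.009
        assert obs.mean() == pytest.approx(10.0, abs=0.03)
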