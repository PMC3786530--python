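"""Delta-method propagation, log-scale intervals and the Monte-Carlo check."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cauticost import (
    CostParams,
    HospitalScenario,
    Intervention,
    RiskParams,
    delta_variance,
    estimate_with_ci,
    expected_counts,
    lognormal_ci,
    monte_carlo_propagation,
    numeric_gradient,
    param_vector,
)
from cauticost.uncertainty import ParamVector

HYP = settings(database=None, derandomize=True, max_examples=100)


def _pv(values, ses=None, names=None):
    values = np.asarray(values, dtype=float)
    ses = np.zeros_like(values) if ses is None else np.asarray(ses, dtype=float)
    names = tuple(names or (f"p{i}" for i in range(len(values))))
    return ParamVector(names=names, values=values, ses=ses)


class TestNumericGradient:
    def test_linear_function(self):
        grad = numeric_gradient(lambda pv: 3.0 * pv.values[0], _pv([2.0]))
        assert grad[0] == pytest.approx(3.0, abs=1e-8)

    def test_constant_function(self):
        grad = numeric_gradient(lambda pv: 7.5, _pv([1.0, 2.0, 3.0]))
        assert np.all(grad == 0.0)

    def test_cost_gradient_wrt_suti_cost_is_suti_count(
        self, hospital, default_risks, default_costs
    ):
        # the cost identity is linear in c_S with coefficient n_suti_only
        pv = param_vector(default_risks, default_costs)

        def objective(p):
            r, q_s, q_b, c_s, c_b = p.values
            risks = default_risks.model_copy(
                update={
                    "bacteriuria_risk": r,
                    "suti_risk_given_bact": q_s,
                    "bsi_risk_given_bact": q_b,
                }
            )
            counts = expected_counts(hospital, risks)
            return c_s * counts.n_suti_only + c_b * counts.n_bsi

        grad = numeric_gradient(objective, pv)
        assert grad[3] == pytest.approx(23.868, rel=1e-6)

    def test_nonfinite_perturbation_reported(self):
        def objective(pv):
            x = pv.values[0]
            return 1.0 / (x - 1.0) if x <= 1.0 else math.inf

        with pytest.raises(FloatingPointError, match="p0"):
            numeric_gradient(objective, _pv([1.0 - 1e-12]))


class TestDeltaVariance:
    def test_zero_ses_give_zero_variance(self, hospital, default_risks, default_costs):
        pv = _pv([0.26, 0.24, 0.036, 911.0, 3824.0])
        assert delta_variance(lambda p: p.values.sum(), pv) == 0.0

    def test_exact_for_linear_map(self):
        pv = _pv([2.0], ses=[0.5])
        var = delta_variance(lambda p: 4.0 * p.values[0], pv)
        assert var == pytest.approx(16.0 * 0.25, rel=1e-9)

    def test_current_cost_se_matches_analytic_sum(
        self, hospital, default_risks, default_costs
    ):
        """The cost map is multilinear, so the delta sum has a closed form."""
        pv = param_vector(default_risks, default_costs)
        R, q_s, q_b, c_s, c_b = pv.values
        k = hospital.admissions * hospital.prop_catheterized
        per_bact = c_s * (q_s - q_b) + c_b * q_b
        analytic = (
            (k * per_bact * pv.ses[0]) ** 2
            + (k * R * c_s * pv.ses[1]) ** 2
            + (k * R * (c_b - c_s) * pv.ses[2]) ** 2
            + (k * R * (q_s - q_b) * pv.ses[3]) ** 2
            + (k * R * q_b * pv.ses[4]) ** 2
        )

        def objective(p):
            r, qs, qb, cs, cb = p.values
            return k * r * (cs * (qs - qb) + cb * qb)

        assert delta_variance(objective, pv) == pytest.approx(analytic, rel=1e-6)
        # relative SE of the current-cost estimate is ~0.73 at the defaults
        cost = k * R * per_bact
        assert math.sqrt(analytic) / cost == pytest.approx(0.727, abs=0.005)


class TestLognormalCI:
    def test_zero_se_degenerates_to_point(self):
        assert lognormal_ci(100.0, 0.0) == (100.0, 100.0)

    def test_published_current_cost_interval(self):
        lo, hi = lognormal_ci(37850.4, 0.7266 * 37850.4, level=0.95)
        assert lo == pytest.approx(9159, rel=0.01)
        assert hi == pytest.approx(156564, rel=0.01)

    def test_multiplicative_symmetry(self):
        lo, hi = lognormal_ci(500.0, 250.0)
        assert hi / 500.0 == pytest.approx(500.0 / lo, rel=1e-12)

    def test_nonpositive_point_warns_degenerate(self):
        with pytest.warns(UserWarning):
            assert lognormal_ci(0.0, 10.0) == (0.0, 0.0)

    @HYP
    @given(
        point=st.floats(1.0, 1e6),
        se1=st.floats(0.0, 1e5),
        se2=st.floats(0.0, 1e5),
    )
    def test_width_monotone_in_se(self, point, se1, se2):
        lo_se, hi_se = sorted([se1, se2])
        narrow = lognormal_ci(point, lo_se)
        wide = lognormal_ci(point, hi_se)
        assert wide[1] - wide[0] >= narrow[1] - narrow[0] - 1e-9
        assert narrow[0] <= point <= narrow[1]

    def test_small_cv_converges_to_normal_interval(self):
        point = 1000.0
        z = 1.959963984540054
        for cv in (0.05, 0.01, 0.001):
            se = cv * point
            lo, hi = lognormal_ci(point, se)
            sym_lo, sym_hi = point - z * se, point + z * se
            rel = max(abs(lo - sym_lo), abs(hi - sym_hi)) / (z * se)
            assert rel < 1.1 * z * cv  # first-order: gap shrinks like z*cv


class TestEstimateWithCI:
    def test_published_current_cost(self, hospital, default_risks, default_costs):
        est = estimate_with_ci(hospital, default_risks, default_costs)
        assert est.point == pytest.approx(37868, rel=0.01)
        assert est.ci_low == pytest.approx(9159, rel=0.01)
        assert est.ci_high == pytest.approx(156564, rel=0.01)

    @pytest.mark.parametrize(
        "f_p, f_d, published, ci",
        [
            (0.40, 0.40, 22653, (5479, 93656)),
            (0.10, 0.10, 6376, (1542, 26360)),
            (0.29, 0.37, 19126, (4626, 79074)),
        ],
    )
    def test_published_savings_estimates(
        self, hospital, default_risks, default_costs, f_p, f_d, published, ci
    ):
        est = estimate_with_ci(
            hospital,
            default_risks,
            default_costs,
            Intervention(placement_reduction=f_p, duration_reduction=f_d),
            quantity="savings",
        )
        assert est.point == pytest.approx(published, rel=0.01)
        assert est.ci_low == pytest.approx(ci[0], rel=0.02)
        assert est.ci_high == pytest.approx(ci[1], rel=0.02)

    def test_all_ses_zero_collapse_interval(self, hospital):
        risks = RiskParams(
            bacteriuria_risk_se=0.0, suti_risk_se=0.0, bsi_risk_se=0.0
        )
        costs = CostParams(suti_cost_se=0.0, bsi_cost_se=0.0)
        est = estimate_with_ci(hospital, risks, costs)
        assert est.se == pytest.approx(0.0, abs=1e-9)
        assert est.ci_low == est.point == est.ci_high


class TestMonteCarloPropagation:
    def test_zero_ses_give_zero_sd(self, hospital):
        risks = RiskParams(bacteriuria_risk_se=0.0, suti_risk_se=0.0, bsi_risk_se=0.0)
        costs = CostParams(suti_cost_se=0.0, bsi_cost_se=0.0)
        mc = monte_carlo_propagation(hospital, risks, costs, n_draws=1000, seed=3)
        # constant draws; SD is zero up to the float rounding of the mean
        assert mc.se == pytest.approx(0.0, abs=1e-6)

    def test_same_seed_identical(self, hospital, default_risks, default_costs):
        a = monte_carlo_propagation(
            hospital, default_risks, default_costs, n_draws=2000, seed=42
        )
        b = monte_carlo_propagation(
            hospital, default_risks, default_costs, n_draws=2000, seed=42
        )
        assert a == b

    def test_small_cv_regime_matches_delta(self, hospital, default_risks):
        """Delta method is first-order exact as CV -> 0."""
        shrink = 0.05
        risks = default_risks.model_copy(
            update={
                "bacteriuria_risk_se": default_risks.bacteriuria_risk_se * shrink,
                "suti_risk_se": default_risks.suti_risk_se * shrink,
                "bsi_risk_se": default_risks.bsi_risk_se * shrink,
            }
        )
        costs = CostParams(suti_cost_se=911 * shrink, bsi_cost_se=3824 * shrink)
        est = estimate_with_ci(hospital, risks, costs)
        mc = monte_carlo_propagation(hospital, risks, costs, n_draws=100_000, seed=7)
        assert mc.se == pytest.approx(est.se, rel=0.05)
        assert mc.clipped_fraction == 0.0
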