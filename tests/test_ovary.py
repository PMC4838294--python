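"""Ovary subsystem: Weibull staging, variance fixed point, growth and steroids."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import weibull_min

from hpolsim.ovary import (
    OvaryState,
    ovary_derivatives,
    ovulation_check,
    oocyte_variance,
    self_consistent_variance,
    sequestration_rate,
    stage_proportions,
)


class TestStageProportions:
    def test_mass_below_first_boundary(self, params):
        S = stage_proportions(0.02, 1e-6, params)
        assert S.proportions[0] == pytest.approx(1.0, abs=1e-6)

    def test_mass_above_last_boundary(self, params):
        S = stage_proportions(7.0, 1e-6, params)
        assert S.S_FOM == pytest.approx(1.0, abs=1e-6)

    def test_matches_quadrature_of_fitted_density(self, params):
        """Stage masses equal numerically integrated Weibull density per interval."""
        S = stage_proportions(1.69, 0.0907, params)
        dist = weibull_min(c=S.weibull.shape, scale=S.weibull.scale)
        edges = [0.0, *params.stage_boundaries(), np.inf]
        for j in range(7):
            hi = edges[j + 1] if np.isfinite(edges[j + 1]) else 20.0
            mass, _ = quad(dist.pdf, edges[j], hi)
            assert S.proportions[j] == pytest.approx(mass, abs=1e-8)
        assert sum(S.proportions) == pytest.approx(1.0, abs=1e-12)

    def test_increasing_mean_shifts_mass_upward(self, params):
        """Stochastic ordering: at fixed variance, larger means give larger S_FOM
        and smaller S_1."""
        v = 0.05
        means = np.linspace(0.5, 6.0, 12)
        fom = [stage_proportions(m, v, params).S_FOM for m in means]
        s1 = [stage_proportions(m, v, params).proportions[0] for m in means]
        assert np.all(np.diff(fom) >= -1e-12)
        assert np.all(np.diff(s1) <= 1e-12)


class TestVariance:
    def test_stage_weighted_variance_values(self, params):
        S = stage_proportions(1.69, 1e-6, params)  # essentially all stage 4... check below
        # direct arithmetic checks on the mixture weights
        from hpolsim.ovary import StageDistribution

        S4 = StageDistribution((0, 0, 0, 1.0, 0, 0, 0), S.weibull, S.boundaries)
        assert oocyte_variance(S4, params) == pytest.approx(0.0907)
        SFOM = StageDistribution((0, 0, 0, 0, 0, 0, 1.0), S.weibull, S.boundaries)
        assert oocyte_variance(SFOM, params) == pytest.approx(0.0067)
        S12 = StageDistribution((0.5, 0.5, 0, 0, 0, 0, 0), S.weibull, S.boundaries)
        assert oocyte_variance(S12, params) == pytest.approx(0.03235)

    def test_fixed_point_small_oocytes(self, params):
        v, S = self_consistent_variance(0.02, params)
        assert v == pytest.approx(params.alpha_OVar_S1, rel=0.05)

    def test_fixed_point_fom(self, params):
        v, S = self_consistent_variance(7.0, params)
        assert v == pytest.approx(params.alpha_OVar_SFOM, rel=1e-3)
        assert S.S_FOM > 0.999

    def test_fixed_point_is_idempotent(self, params):
        v, _ = self_consistent_variance(1.3, params)
        v2, _ = self_consistent_variance(1.3, params, v_init=v)
        assert v2 == pytest.approx(v, abs=1e-8)


class TestSequestration:
    def test_basal_rate_all_vitellogenic(self, params):
        S = stage_proportions(2.5, 1e-4, params)  # all mass in stages 3-6
        assert S.vitellogenic_fraction() == pytest.approx(1.0, abs=1e-6)
        assert sequestration_rate(0.0, S, params) == pytest.approx(170.0, rel=1e-6)

    def test_half_maximal_fsh_boost(self, params):
        S = stage_proportions(2.5, 1e-4, params)
        assert sequestration_rate(13.7, S, params) == pytest.approx(255.0, rel=1e-6)

    def test_no_vitellogenic_mass_no_uptake(self, params):
        S = stage_proportions(0.05, 1e-6, params)
        assert sequestration_rate(50.0, S, params) == pytest.approx(0.0, abs=1e-4)


def _ovary_state(O_Avg=1.0, E2=0.0, DHP=0.0, fsh=0.0, lh=0.0, m=5):
    return OvaryState(
        O_Avg=O_Avg, E2=E2, DHP=DHP,
        fsh_chain=np.full(m, fsh), lh_chain=np.full(m, lh),
    )


class TestOvaryDerivatives:
    def test_e2_production_rate_and_steady_state(self, params):
        """Delayed FSH = 10 with all mass in stage 4: production and steady state
        follow the clearance-volume balance."""
        S = stage_proportions(1.45, 1e-4, params)  # all stage 4 (1.17-1.69)
        assert S.proportions[3] == pytest.approx(1.0, abs=1e-5)
        state = _ovary_state(O_Avg=1.45, fsh=10.0)
        d = ovary_derivatives(state, 0.0, 0.0, 0.0, S, params)
        rate = params.n_oocyte * (params.k_E2 + 10.0 * params.Cl_E2_S4) / params.V_E2
        assert rate == pytest.approx(0.3094, abs=2e-4)
        assert d.E2 == pytest.approx(rate, rel=1e-4)
        e2_ss = params.n_oocyte * (params.k_E2 + 10.0 * params.Cl_E2_S4) / params.Cl_E2
        assert e2_ss == pytest.approx(3.670, abs=2e-3)
        state_ss = _ovary_state(O_Avg=1.45, E2=e2_ss, fsh=10.0)
        assert ovary_derivatives(state_ss, 0.0, 0.0, 0.0, S, params).E2 == pytest.approx(0.0, abs=1e-10)

    def test_dhp_pure_decay_without_delayed_lh(self, params):
        S = stage_proportions(1.45, 1e-4, params)
        state = _ovary_state(O_Avg=1.45, DHP=50.0, lh=0.0)
        d = ovary_derivatives(state, 0.0, 0.0, 0.0, S, params)
        assert d.DHP == pytest.approx(-params.Cl_DHP * 50.0 / params.V_DHP)

    def test_dhp_production_linear_in_delayed_lh(self, params):
        S = stage_proportions(6.5, 1e-4, params)  # all FOM
        d1 = ovary_derivatives(_ovary_state(O_Avg=6.5, lh=1.0), 0, 0, 0, S, params).DHP
        d2 = ovary_derivatives(_ovary_state(O_Avg=6.5, lh=2.0), 0, 0, 0, S, params).DHP
        assert d2 == pytest.approx(2.0 * d1)

    def test_nonvitellogenic_growth_constant(self, params):
        S = stage_proportions(0.05, 1e-6, params)  # all stage 1
        d = ovary_derivatives(_ovary_state(O_Avg=0.05), 0.0, 0.0, 0.0, S, params)
        assert d.O_Avg == pytest.approx(params.k_NV_OAvg, rel=1e-5)  # 0.00067 mm/hr

    def test_growth_nonnegative_with_nonnegative_vtg(self, params):
        for o in (0.3, 1.2, 2.8, 6.0):
            S = stage_proportions(o, 0.05, params)
            d = ovary_derivatives(_ovary_state(O_Avg=o), 0.0, 0.0, 5.0, S, params)
            assert d.O_Avg >= 0.0


class TestOvulationCheck:
    @pytest.mark.parametrize(
        "dhp,s_fom,expected",
        [
            (121.0, 0.99, True),
            (119.0, 0.99, False),
            (500.0, 0.97, False),
            (120.0, 0.98, True),  # thresholds are inclusive
        ],
    )
    def test_dual_threshold(self, params, dhp, s_fom, expected):
        assert ovulation_check(dhp, s_fom, params) is expected
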