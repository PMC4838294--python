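"""Engine: state assembly, staging table accuracy, integration and event logic."""

import dataclasses

import numpy as np
import pytest

import hpolsim as h
from hpolsim.engine import (
    PRIMARY_NAMES,
    SimulationOptions,
    StagingTable,
    StateLayout,
    assemble_rhs,
    default_initial_state,
    find_extrema_lags,
    lh_release_episodes,
    simulate,
)
from hpolsim.gnrh import default_gnrh_driver
from hpolsim.ovary import self_consistent_variance


class TestStateLayout:
    def test_full_model_dimensions(self):
        lay = StateLayout(m=5, vtg_model="full")
        assert lay.n_states == 15 + 3 * 5
        assert len(lay.names()) == lay.n_states
        assert lay.names()[:15] == PRIMARY_NAMES

    def test_simplified_adds_fourth_chain(self):
        lay = StateLayout(m=4, vtg_model="simplified")
        assert lay.n_states == 15 + 4 * 4
        assert lay.chain_slice("e2_vtg").stop == lay.n_states


class TestInitialState:
    def test_prevtg_start_and_basal_levels(self, params):
        opts = SimulationOptions()
        y0 = default_initial_state(params, options=opts)
        lay = opts.layout()
        ix = lay.index
        assert y0[ix["O_Avg"]] == 0.15
        assert y0[ix["mR"]] == pytest.approx(60.0)
        assert y0[ix["DHP"]] == 0.0
        assert y0[ix["LH_P"]] == 0.0
        # chains initialised to their drivers' initial values
        np.testing.assert_allclose(y0[lay.chain_slice("e2_mlh")], y0[ix["E2"]])
        np.testing.assert_allclose(y0[lay.chain_slice("fsh_e2")], y0[ix["FSH_P"]])
        # nearly all oocytes start pre-vitellogenic
        _, S = self_consistent_variance(0.15, params)
        assert S.proportions[0] + S.proportions[1] > 0.9

    def test_start_is_near_quasi_steady_state(self, params):
        opts = SimulationOptions()
        y0 = default_initial_state(params, options=opts)
        rhs = assemble_rhs(params, default_gnrh_driver(), opts)
        dy = rhs(0.0, y0)
        ix = opts.layout().index
        for name in ("mFSH", "mLH", "FSH_P", "mR"):
            scale = max(abs(y0[ix[name]]), 1.0)
            assert abs(dy[ix[name]]) < 1e-6 * scale, name
        # R starts at its E2-free steady state; the only residual flux is the
        # slow re-equilibration toward binding at the small basal E2
        assert abs(dy[ix["R"]]) < 1.0


class TestStagingTable:
    def test_matches_exact_fixed_point(self, params):
        table = StagingTable(params)
        for o in (0.11, 0.45, 0.9, 1.31, 1.8, 2.7, 4.1, 5.25, 6.3):
            v_exact, S_exact = self_consistent_variance(o, params)
            assert float(table.variance(o)) == pytest.approx(v_exact, abs=1e-6)
            np.testing.assert_allclose(
                table.stages(o), S_exact.proportions, atol=1e-6
            )

    def test_stage_sums_to_one_everywhere(self, params):
        table = StagingTable(params)
        S = table.stages(np.linspace(0.05, 9.5, 400))
        np.testing.assert_allclose(S.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(S >= -1e-12)


class TestRhsStructure:
    def test_sequestration_ablation_decouples_growth(self, params):
        """With the sequestration clearance off, diameter growth reduces to the
        non-vitellogenic term regardless of plasma VTG."""
        p = dataclasses.replace(params, Cl_VTG_Seq=1e-300)
        opts = SimulationOptions()
        rhs = assemble_rhs(p, default_gnrh_driver(), opts)
        lay = opts.layout()
        y = default_initial_state(p, options=opts)
        y[lay.index["O_Avg"]] = 2.5  # vitellogenic mean
        y[lay.index["VTG_P"]] = 50.0
        dy = rhs(0.0, y)
        table = StagingTable(p)
        S = table.stages(2.5)
        assert dy[lay.index["O_Avg"]] == pytest.approx(
            p.k_NV_OAvg * (S[0] + S[1] + S[6]), rel=1e-9
        )

    def test_nonfinite_state_raises_with_snapshot(self, params):
        opts = SimulationOptions()
        rhs = assemble_rhs(params, default_gnrh_driver(), opts)
        y = default_initial_state(params, options=opts)
        y[0] = np.nan
        with pytest.raises(ArithmeticError, match="non-finite"):
            rhs(0.0, y)


class TestSimulateShort:
    def test_output_grid_and_shapes(self, short_run):
        assert short_run.t_hours[0] == 0.0
        np.testing.assert_allclose(np.diff(short_run.t_hours), 1.0)
        assert short_run.states.shape == (len(short_run.t_hours), short_run.layout.n_states)
        for name in ("S_1", "S_FOM", "O_Var", "Seq", "R_LH", "GnRH"):
            assert len(short_run.derived[name]) == len(short_run.t_hours)

    def test_stage_proportions_sum_to_one_along_trajectory(self, short_run):
        total = sum(short_run.derived[f"S_{j}"] for j in range(1, 7))
        total = total + short_run.derived["S_FOM"]
        np.testing.assert_allclose(total, 1.0, atol=1e-9)

    def test_no_ovulation_flag(self, short_run):
        assert short_run.no_ovulation
        assert short_run.ovulation_times_days() == []

    def test_unreachable_threshold_never_ovulates(self, params):
        p = dataclasses.replace(params, DHP_final=1e12)
        r = simulate(p, options=SimulationOptions(duration_days=20.0))
        assert r.no_ovulation

    def test_states_remain_essentially_nonnegative(self, short_run):
        atol = short_run.layout.atol_vector(short_run.options.atol)
        assert np.all(short_run.states >= -10.0 * atol)


class TestExtremaLags:
    def test_identical_series_zero_lag(self):
        t = np.arange(0.0, 200.0, 1.0 / 24.0)
        a = np.sin(2 * np.pi * t / 80.0) + 2.0
        out = find_extrema_lags(t, a, a)
        assert out and all(abs(lag) < 0.25 for _, _, lag in out)

    def test_constructed_shift_recovered(self):
        t = np.arange(0.0, 400.0, 1.0 / 24.0)
        a = np.exp(-((t - 150.0) ** 2) / (2 * 30.0**2))
        b = np.exp(-((t - 186.0) ** 2) / (2 * 30.0**2))
        out = find_extrema_lags(t, a, b)
        assert len(out) == 1
        assert out[0][2] == pytest.approx(36.0, abs=0.5)

    def test_no_extrema_gives_empty_list(self):
        t = np.linspace(0.0, 10.0, 100)
        assert find_extrema_lags(t, t, t) == []


class TestBaselineRun:
    def test_two_release_episodes_premature_then_surge(self, baseline):
        """The spillover release opens twice: a premature rise when E2 first
        declines from its plateau, and the pre-ovulatory surge at the final
        E2 collapse (which has the larger LH peak)."""
        eps = lh_release_episodes(baseline)
        assert len(eps) == 2
        assert eps[1][2] > eps[0][2]

    def test_main_surge_accompanies_e2_decline_through_gate(self, baseline, params):
        eps = lh_release_episodes(baseline)
        onset = eps[-1][0]
        t = baseline.t_days
        e2 = baseline.series("E2")
        i = np.searchsorted(t, onset)
        window = slice(i, min(i + 10 * 24, len(t)))
        assert e2[window].min() < params.T_E2_LH < e2[i] + 5.0
        # E2 is falling at surge onset
        assert e2[i + 24] < e2[i - 24]

    def test_events_are_ordered_and_typed(self, baseline):
        kinds = {k for k, _ in baseline.events}
        assert "ovulation" in kinds and "lh_release_onset" in kinds
        times = [t for _, t in baseline.events]
        assert times == sorted(times)
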