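"""Stressor scenarios, GnRH recovery, stage-boundary rescaling, subsystem fits."""

import numpy as np
import pytest

import hpolsim as h
from hpolsim.calibration import (
    ObservedSeries,
    calibrate_gnrh_from_fsh,
    fit_subsystem,
    make_synthetic_series,
    recalibrate_stage_boundaries,
)
from hpolsim.scenarios import prevtg_majority_gate, trenbolone_scenario


class TestTrenboloneScenario:
    def test_clearance_variant_multipliers(self):
        sc = trenbolone_scenario("+clearance")
        assert sc.multipliers == {"Cl_E2_S4": 0.54, "Cl_E2_S5": 0.54, "Cl_E2": 1.41}
        assert [(n, f) for n, f, _ in sc.gated] == [("ks_FSH", 4.0)]

    def test_mvtg_variant_multipliers(self):
        sc = trenbolone_scenario("+mvtg")
        assert sc.multipliers["ks_mVTG"] == 0.6
        assert "Cl_E2" not in sc.multipliers

    def test_both_variant_combines(self):
        sc = trenbolone_scenario("both")
        assert sc.multipliers["Cl_E2"] == 1.41 and sc.multipliers["ks_mVTG"] == 0.6

    def test_unknown_variant(self):
        with pytest.raises(ValueError):
            trenbolone_scenario("mega")

    def test_apply_composes_with_perturbation(self, params):
        sc = trenbolone_scenario("both")
        p = sc.apply(params)
        assert p.Cl_E2_S4 == pytest.approx(0.0027 * 0.54)
        assert p.Cl_E2 == pytest.approx(31.02)

    def test_gate_is_smooth_indicator_of_prevtg_majority(self):
        gate = prevtg_majority_gate()
        S = np.zeros(7)
        S[0] = 0.8
        assert gate(S) == 1.0
        S[0] = 0.2
        assert gate(S) == 0.0
        S[0] = 0.5
        assert 0.0 < gate(S) < 1.0


class TestStageBoundaryRecalibration:
    def test_round_trip_at_default_maximum(self, params):
        o_m_def = (params.s_6 - params.s_2) / 0.84  # ~5.595 mm
        new = recalibrate_stage_boundaries(o_m_def, params)
        np.testing.assert_allclose(new, (1.17, 1.69, 3.4, 5.3), atol=1e-9)

    def test_published_recalibration_example(self, params):
        s3, s4, s5, s6 = recalibrate_stage_boundaries(5.81, params)
        assert s3 == pytest.approx(1.19, abs=0.05)
        assert s4 == pytest.approx(1.74, abs=0.05)
        assert s5 == pytest.approx(3.51, abs=0.05)
        assert s6 == pytest.approx(5.48, abs=0.05)

    def test_vitellogenic_growth_fractions(self, params):
        """Stages 3-6 account for ~10, 9, 31 and 34 percent of total growth."""
        s = params.stage_boundaries()
        o_m_def = (s[5] - s[1]) / 0.84
        fractions = np.diff(s[1:]) / o_m_def * 100.0
        np.testing.assert_allclose(fractions, [10, 9, 31, 34], atol=0.5)

    def test_linearity_in_target(self, params):
        a = np.array(recalibrate_stage_boundaries(4.0, params))
        b = np.array(recalibrate_stage_boundaries(8.0, params))
        mid = np.array(recalibrate_stage_boundaries(6.0, params))
        np.testing.assert_allclose(mid - params.s_2, ((a - params.s_2) + (b - params.s_2)) / 2)

    def test_invalid_target(self, params):
        with pytest.raises(ValueError):
            recalibrate_stage_boundaries(-1.0, params)


class TestGnRHCalibration:
    def test_constant_fsh_recovers_closed_form(self, params):
        fbar = 5.0
        days = np.linspace(0.0, 300.0, 31)
        series = ObservedSeries(days=days, values=np.full_like(days, fbar), analyte="FSH_P")
        driver = calibrate_gnrh_from_fsh(series, params)
        mfsh = params.Cl_FSH * fbar / (params.w_Pit * params.ks_FSH)
        expected = (params.kd_mFSH * mfsh / params.ks_mFSH - 1.0) / params.alpha_mFSH_GnRH
        mid = driver(150.0 * 24.0)
        assert mid == pytest.approx(expected, rel=1e-6)

    def test_round_trip_through_simulation(self, baseline, params):
        """Driver -> FSH -> recovered driver -> FSH agrees within 10% RMS."""
        obs = make_synthetic_series(baseline, "FSH_P", cadence_days=14.0, noise_cv=0.0)
        driver = calibrate_gnrh_from_fsh(obs, params)
        replay = h.simulate(params, driver, h.SimulationOptions(duration_days=365.0))
        f0 = baseline.series("FSH_P")
        f1 = replay.series("FSH_P")
        rms = np.sqrt(np.mean((f1 - f0) ** 2)) / np.sqrt(np.mean(f0**2))
        assert rms < 0.10

    def test_zero_fsh_clips_and_warns(self, params):
        days = np.linspace(0.0, 300.0, 31)
        series = ObservedSeries(days=days, values=np.zeros_like(days), analyte="FSH_P")
        with pytest.warns(UserWarning, match="clipped"):
            driver = calibrate_gnrh_from_fsh(series, params)
        assert np.all(driver.values == 0.0)

    def test_too_few_points(self, params):
        series = ObservedSeries(days=np.array([0.0, 50.0, 100.0]),
                                values=np.array([1.0, 2.0, 1.0]), analyte="FSH_P")
        with pytest.raises(ValueError, match="at least 5"):
            calibrate_gnrh_from_fsh(series, params)


class TestSubsystemFitting:
    def _e2_observations(self, baseline, rng, noise_cv):
        obs = [
            make_synthetic_series(baseline, "E2", cadence_days=7.0, noise_cv=noise_cv, rng=rng),
        ]
        # drivers: the delayed FSH seen by the ovary, and the stage proportions
        lay = baseline.layout
        delayed = baseline.states[:, lay.chain_slice("fsh_e2")][:, -1]
        t = baseline.t_days
        pick = np.arange(0, len(t), 24)  # daily driver sampling keeps splines tight
        obs.append(ObservedSeries(days=t[pick], values=np.clip(delayed[pick], 0, None),
                                  analyte="FSH_delayed"))
        for j in range(2, 7):
            obs.append(ObservedSeries(days=t[pick],
                                      values=np.clip(baseline.derived[f"S_{j}"][pick], 0, None),
                                      analyte=f"S_{j}"))
        return obs

    def test_noise_free_recovery_is_exact(self, baseline, params, rng):
        obs = self._e2_observations(baseline, rng, noise_cv=0.0)
        fit = fit_subsystem(obs, "e2", ["Cl_E2"], params,
                            x0={"Cl_E2": 30.0})
        assert fit.converged
        assert fit.estimates["Cl_E2"] == pytest.approx(params.Cl_E2, rel=0.01)
        assert fit.residual < 0.05  # ng/ml RMS against a ~40 ng/ml peak signal

    def test_recovery_within_5_percent_at_5_percent_noise(self, baseline, params):
        rng = np.random.default_rng(7)
        obs = self._e2_observations(baseline, rng, noise_cv=0.05)
        fit = fit_subsystem(obs, "e2", ["Cl_E2"], params, x0={"Cl_E2": 28.0})
        assert fit.converged
        assert fit.estimates["Cl_E2"] == pytest.approx(params.Cl_E2, rel=0.05)

    def test_free_parameter_outside_subsystem(self, baseline, params, rng):
        obs = self._e2_observations(baseline, rng, noise_cv=0.0)
        with pytest.raises(ValueError, match="not part of subsystem"):
            fit_subsystem(obs, "e2", ["kd_mFSH"], params)

    def test_unknown_subsystem(self, params):
        with pytest.raises(KeyError):
            fit_subsystem([], "nope", [], params)


class TestSyntheticSeries:
    def test_cadence_and_noise(self, short_run, rng):
        s = make_synthetic_series(short_run, "FSH_P", cadence_days=7.0, noise_cv=0.1, rng=rng)
        assert np.all(np.diff(s.days) > 0)
        assert np.all(s.values >= 0)
        assert len(s.days) == len(short_run.t_days[::7 * 24])

    def test_noise_free_sampling_matches_trajectory(self, short_run):
        s = make_synthetic_series(short_run, "E2", cadence_days=5.0, noise_cv=0.0)
        np.testing.assert_allclose(s.values, short_run.series("E2")[::5 * 24])
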