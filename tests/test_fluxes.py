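"""Non-steady-state Steele flux estimation."""

import numpy as np
import pytest

import hypoclamp as hc
from hypoclamp.exceptions import EstimationError
from hypoclamp.fluxes import (FluxProfile, SteeleConfig, egp, estimate_fluxes,
                              fasting_flux_metrics, oral_ra,
                              postprandial_flux_metrics,
                              smooth_and_differentiate, steele_ratot,
                              steele_rd)
from hypoclamp.records import SampledSeries
from hypoclamp.units import GLUCOSE_MMOL_L_TO_MG_ML


def _series(times, values, channel="glucose", units="mmol/l"):
    return SampledSeries(np.asarray(times, float),
                         np.asarray(values, float), channel, units)


class TestSmoothing:
    def test_constant_series_zero_derivative(self):
        s = _series(np.arange(0, 100, 10), np.full(10, 5.0))
        _, sm, dv = smooth_and_differentiate(s, SteeleConfig())
        assert sm == pytest.approx(5.0, abs=1e-9)
        assert np.max(np.abs(dv)) < 1e-9

    @pytest.mark.parametrize("smoother", ["spline_gcv", "spline_fixed",
                                          "local_poly"])
    def test_line_recovers_exact_slope(self, smoother):
        t = np.arange(0, 101, 10.0)
        s = _series(t, 2.0 + 0.1 * t)
        _, sm, dv = smooth_and_differentiate(s, SteeleConfig(smoother=smoother))
        assert dv == pytest.approx(0.1, abs=1e-6)

    def test_quadratic_derivative_mid_window(self):
        t = np.arange(-20, 181, 10.0)
        s = _series(t, 5.0 + 0.02 * t + 1e-4 * t * t)
        grid, _, dv = smooth_and_differentiate(s, SteeleConfig())
        mid = (grid >= 40) & (grid <= 120)
        analytic = 0.02 + 2e-4 * grid[mid]
        assert np.max(np.abs(dv[mid] - analytic) / analytic) < 0.05

    def test_too_few_samples(self):
        s = _series([0.0, 10.0, 20.0], [1.0, 2.0, 3.0])
        with pytest.raises(EstimationError, match="at least 4"):
            smooth_and_differentiate(s, SteeleConfig())

    def test_fixed_penalty_smoother_is_linear(self):
        cfg = SteeleConfig(smoother="spline_fixed", lam=25.0)
        t = np.arange(0, 121, 10.0)
        rng = np.random.default_rng(3)
        a, b = rng.normal(5, 1, len(t)), rng.normal(0, 0.5, len(t))
        _, sa, da = smooth_and_differentiate(_series(t, a), cfg)
        _, sb, db = smooth_and_differentiate(_series(t, b), cfg)
        _, sab, dab = smooth_and_differentiate(_series(t, a + b), cfg)
        assert sab == pytest.approx(sa + sb, abs=1e-9)
        assert dab == pytest.approx(da + db, abs=1e-9)


class TestSteeleSteadyState:
    """Constant inputs: every flux equals its closed form to 1e-9."""

    t = np.arange(-20, 121, 10.0)

    def test_ratot_closed_form(self):
        glucose = _series(self.t, np.full_like(self.t, 4.9))
        z1 = _series(self.t, np.full_like(self.t, 0.016484), "z1", "")
        out = steele_ratot(glucose, z1, F=0.03)
        expected = 0.03 * (1.0 / 0.016484 + 1.0)
        assert out.values == pytest.approx(expected, abs=1e-9)
        assert round(float(out.values[0]), 2) == 1.85   # fasting-table scale

    def test_zero_infusion_zero_turnover(self):
        glucose = _series(self.t, np.full_like(self.t, 4.9))
        z1 = _series(self.t, np.full_like(self.t, 0.0165), "z1", "")
        out = steele_ratot(glucose, z1, F=0.0)
        assert out.values == pytest.approx(0.0, abs=1e-9)

    def test_nonpositive_enrichment_rejected(self):
        glucose = _series(self.t, np.full_like(self.t, 4.9))
        z1 = _series(self.t, np.linspace(0.02, -0.01, len(self.t)), "z1", "")
        with pytest.raises(EstimationError, match="non-positive"):
            steele_ratot(glucose, z1, F=0.03)

    def test_rd_equals_ratot_at_steady_state(self):
        glucose = _series(self.t, np.full_like(self.t, 4.9))
        ratot = _series(self.t, np.full_like(self.t, 1.85), "ratot",
                        "mg/kg/min")
        out = steele_rd(ratot, glucose)
        assert out.values == pytest.approx(1.85, abs=1e-9)

    def test_rd_hand_value_with_falling_glucose(self):
        # dC/dt = -0.01 mg/ml/min with p*V = 104 ml/kg: Rd = 2.0 + 1.04
        slope = -0.01 / GLUCOSE_MMOL_L_TO_MG_ML          # mmol/l per min
        glucose = _series(self.t, 6.0 + slope * self.t)
        ratot = _series(self.t, np.full_like(self.t, 2.0), "ratot",
                        "mg/kg/min")
        cfg = SteeleConfig(pool_fraction=0.65, v_steele=160.0)
        out = steele_rd(ratot, glucose, cfg)
        assert out.values == pytest.approx(3.04, abs=1e-6)

    def test_oral_ra_zero_without_label(self):
        glucose = _series(self.t, np.full_like(self.t, 5.5))
        z1 = _series(self.t, np.full_like(self.t, 0.016), "z1", "")
        z2 = _series(self.t, np.zeros_like(self.t), "z2", "")
        rd = _series(self.t, np.full_like(self.t, 2.0), "rd", "mg/kg/min")
        out = oral_ra(glucose, z1, z2, rd, e_oral=0.015)
        assert out.values == pytest.approx(0.0, abs=1e-12)

    def test_oral_ra_steady_closed_form(self):
        glucose = _series(self.t, np.full_like(self.t, 5.5))
        z1 = _series(self.t, np.full_like(self.t, 0.016), "z1", "")
        z2 = _series(self.t, np.full_like(self.t, 0.012), "z2", "")
        rd = _series(self.t, np.full_like(self.t, 2.0), "rd", "mg/kg/min")
        out = oral_ra(glucose, z1, z2, rd, e_oral=0.015)
        c = 5.5 * GLUCOSE_MMOL_L_TO_MG_ML
        c2 = c * 0.012 / (1 + 0.016 + 0.012)
        expected = 2.0 * (c2 / c) / 0.015
        assert out.values == pytest.approx(expected, abs=1e-9)

    def test_negative_z2_rejected(self):
        glucose = _series(self.t, np.full_like(self.t, 5.5))
        z1 = _series(self.t, np.full_like(self.t, 0.016), "z1", "")
        z2v = np.zeros_like(self.t)
        z2v[3] = -0.001
        rd = _series(self.t, np.full_like(self.t, 2.0), "rd", "mg/kg/min")
        with pytest.raises(EstimationError, match="non-negative"):
            oral_ra(glucose, z1, _series(self.t, z2v, "z2", ""), rd, 0.015)


class TestEgpPartition:
    def test_fasting_identity(self):
        """Fasting: EGP = Ra_tot - F; the 0.03 gap between a fasting
        turnover of 1.85 and production of 1.82 is the tracer infusion."""
        assert egp(1.85, 0.0, 0.0, F=0.03) == pytest.approx(1.82, abs=1e-12)

    def test_pure_tracer_turnover_gives_zero(self):
        assert egp(0.03, 0.0, 0.0, F=0.03) == pytest.approx(0.0, abs=1e-12)

    def test_series_partition(self):
        t = np.arange(0, 50, 10.0)
        ratot = _series(t, np.full_like(t, 3.0), "ratot", "mg/kg/min")
        rao = np.full_like(t, 1.0)
        gir = np.full_like(t, 0.5)
        out = egp(ratot, rao, gir, F=0.03)
        assert out.values == pytest.approx(3.0 - 0.03 - 1.0 - 0.5)


@pytest.fixture(scope="module")
def profile_and_truth(cn_subject_clean, protocol, matched_steele):
    rec, truth = cn_subject_clean
    profile = estimate_fluxes(rec, protocol, matched_steele)
    return profile, truth


class TestRecoveryOnSimulatedSubject:
    """The estimator against the simulator's ground truth (noise-free
    default subject, volume model matched to the simulated pool)."""

    @staticmethod
    def _true_on(profile, truth, arr):
        return np.interp(profile.times, truth.times, arr)

    def test_ratot_tracks_truth(self, profile_and_truth):
        profile, truth = profile_and_truth
        m = (profile.times >= 0) & (profile.times <= 85)
        t_true = self._true_on(profile, truth, truth.ra_tot)
        rel = (profile.ratot[m] - t_true[m]) / t_true[m]
        assert np.sqrt(np.mean(rel ** 2)) < 0.10

    def test_rd_tracks_truth(self, profile_and_truth):
        profile, truth = profile_and_truth
        m = (profile.times >= 0) & (profile.times <= 170)
        t_true = self._true_on(profile, truth, truth.rd)
        rel = (profile.rd[m] - t_true[m]) / t_true[m]
        assert np.sqrt(np.mean(rel ** 2)) < 0.10

    def test_rao_auc_within_ten_percent(self, profile_and_truth):
        profile, truth = profile_and_truth
        t = profile.times
        m = (t >= 0) & (t <= 85)
        est = np.trapezoid(profile.ra_o[m], t[m])
        tru = np.trapezoid(self._true_on(profile, truth, truth.ra_o)[m], t[m])
        assert abs(est - tru) / tru < 0.10

    def test_egp_rmse_bounded(self, profile_and_truth):
        profile, truth = profile_and_truth
        t = profile.times
        m = (t >= 0) & (t <= 170)
        err = profile.egp[m] - self._true_on(profile, truth, truth.egp)[m]
        assert np.sqrt(np.mean(err ** 2)) <= 0.3

    def test_recovery_within_five_points_of_truth(self, profile_and_truth,
                                                  protocol):
        profile, truth = profile_and_truth
        bw = truth.params.bw
        metrics = postprandial_flux_metrics(profile, protocol, bw)
        t = truth.times
        m = (t >= 0) & (t <= 85)
        truth_rec = np.trapezoid(truth.ra_o[m], t[m]) * bw \
            / protocol.oral_dose * 100.0
        assert abs(metrics["recovery_percent"] - truth_rec) <= 5.0

    def test_fasting_estimates_near_basal(self, profile_and_truth):
        profile, truth = profile_and_truth
        fast = fasting_flux_metrics(profile)
        assert fast["fasting_egp"] == pytest.approx(truth.params.egp_b,
                                                    rel=0.05)
        assert fast["fasting_ratot"] == pytest.approx(
            truth.params.egp_b + 0.03, rel=0.05)


class TestPostprandialMetrics:
    def _profile(self, egp_values):
        t = np.arange(-20.0, 91.0, 1.0)
        z = np.zeros_like(t)
        return FluxProfile(times=t, ratot=z, rd=z, ra_o=z,
                           egp=np.asarray(egp_values, float))

    def test_constant_egp_no_suppression(self, protocol):
        t = np.arange(-20.0, 91.0, 1.0)
        prof = self._profile(np.full_like(t, 1.8))
        out = postprandial_flux_metrics(prof, protocol, bw=78.0)
        assert out["egp_suppression_t15"] == pytest.approx(0.0, abs=1e-12)

    def test_hand_suppression_value(self, protocol):
        t = np.arange(-20.0, 91.0, 1.0)
        egp_v = np.where(t < 5, 1.8, np.nan)
        # linear fall from 1.8 at t5 to 1.35 at t15, flat after
        egp_v = np.interp(t, [-20.0, 5.0, 15.0, 90.0],
                          [1.8, 1.8, 1.35, 1.35])
        prof = self._profile(egp_v)
        out = postprandial_flux_metrics(prof, protocol, bw=78.0)
        assert out["egp_suppression_t15"] == pytest.approx(-0.25, abs=1e-12)

    def test_profile_must_cover_window(self, protocol):
        t = np.arange(0.0, 50.0, 1.0)
        z = np.zeros_like(t)
        prof = FluxProfile(times=t, ratot=z, rd=z, ra_o=z, egp=z + 1.0)
        with pytest.raises(EstimationError, match="cover"):
            postprandial_flux_metrics(prof, protocol, bw=78.0)
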