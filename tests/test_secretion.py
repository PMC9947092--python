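"""C-peptide deconvolution and insulin sensitivity/clearance metrics."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from hypoclamp.exceptions import EstimationError, IdentifiabilityError
from hypoclamp.records import SampledSeries
from hypoclamp.secretion import (CPeptideKinetics, DeconvConfig,
                                 cpeptide_impulse_response, homa_classic,
                                 insulin_sensitivity_index, isr_deconvolve,
                                 posthepatic_clearance,
                                 total_insulin_clearance)


@pytest.fixture(scope="module")
def kin():
    return CPeptideKinetics.population()


class TestImpulseResponse:
    def test_initial_value_is_inverse_volume(self, kin):
        assert cpeptide_impulse_response(kin, 0.0) == \
            pytest.approx(1.0 / kin.v1)

    def test_integral_matches_closed_form(self, kin):
        t = np.linspace(0, 2400, 240001)
        integral = np.trapezoid(kin.impulse_response(t), t)
        assert integral == pytest.approx(1.0 / (kin.k01 * kin.v1), abs=1e-6)

    def test_degenerate_single_exponential(self):
        k = CPeptideKinetics(k01=0.06, k12=0.0, k21=0.0, v1=5.0)
        t = np.linspace(0, 100, 11)
        assert k.impulse_response(t) == \
            pytest.approx(np.exp(-0.06 * t) / 5.0, rel=1e-12)

    def test_half_life_round_trip(self):
        k = CPeptideKinetics.from_half_lives(4.95, 29.2, 0.76, v1=5.0)
        lam1, lam2, f = k._eigen()
        assert np.log(2) / lam1 == pytest.approx(4.95, rel=1e-9)
        assert np.log(2) / lam2 == pytest.approx(29.2, rel=1e-9)
        assert f == pytest.approx(0.76, rel=1e-9)

    def test_causal(self, kin):
        assert kin.impulse_response(-5.0) == 0.0


class TestDeconvolution:
    def test_zero_input_zero_isr(self, kin):
        t = np.arange(0, 90.1, 10.0)
        cp = SampledSeries(t, np.zeros_like(t), "c_peptide", "pmol/l")
        res = isr_deconvolve(cp, kin, bw=78.0)
        assert np.all(res.isr == 0.0)

    def test_constant_cpeptide_steady_secretion(self, kin):
        """Sustained C-peptide C implies ISR = k01 V1 C / BW."""
        t = np.arange(0, 121, 10.0)
        cbar, bw = 450.0, 78.0
        cp = SampledSeries(t, np.full_like(t, cbar), "c_peptide", "pmol/l")
        res = isr_deconvolve(cp, kin, DeconvConfig(lam=1.0), bw=bw)
        assert res.isr == pytest.approx(cbar * kin.k01 * kin.v1 / bw,
                                        rel=1e-6)

    def test_too_few_samples(self, kin):
        t = np.arange(0, 41, 10.0)
        cp = SampledSeries(t, np.full_like(t, 400.0), "c_peptide", "pmol/l")
        with pytest.raises(EstimationError, match="6 samples"):
            isr_deconvolve(cp, kin, bw=78.0)

    @staticmethod
    def _forward_cpeptide(kin, knots, rates, bw, obs_times):
        """Independent forward model: integrate the two-compartment ODE
        under piecewise-constant secretion."""
        def isr(t):
            j = int(np.clip(np.searchsorted(knots, t, side="right") - 1,
                            0, len(rates) - 1))
            return rates[j]

        def rhs(t, y):
            q1, q2 = y
            return [isr(t) * bw - (kin.k01 + kin.k21) * q1 + kin.k12 * q2,
                    kin.k21 * q1 - kin.k12 * q2]

        q1b = rates[0] * bw / kin.k01
        q2b = kin.k21 * q1b / kin.k12
        sol = solve_ivp(rhs, (knots[0], knots[-1]), [q1b, q2b],
                        t_eval=obs_times, rtol=1e-10, atol=1e-10,
                        max_step=1.0)
        return sol.y[0] / kin.v1

    def test_noise_free_round_trip(self, kin):
        """Forward-convolved piecewise-constant ISR is recovered to
        better than 1% as the penalty vanishes."""
        bw = 78.0
        knots = np.arange(0.0, 180.1, 5.0)
        rates = np.where((knots[:-1] >= 30) & (knots[:-1] < 60), 8.0, 1.5)
        obs_t = np.arange(0.0, 180.1, 5.0)
        obs = self._forward_cpeptide(kin, knots, rates, bw, obs_t)
        cp = SampledSeries(obs_t, obs, "c_peptide", "pmol/l")
        res = isr_deconvolve(cp, kin, DeconvConfig(lam=1e-8), bw=bw)
        rel = np.linalg.norm(res.isr - rates) / np.linalg.norm(rates)
        assert rel < 0.01

    def test_noisy_pulse_auc_within_ten_percent(self, kin):
        bw = 78.0
        knots = np.arange(0.0, 180.1, 5.0)
        rates = np.where((knots[:-1] >= 30) & (knots[:-1] < 60), 8.0, 1.5)
        obs_t = np.arange(0.0, 180.1, 5.0)
        obs = self._forward_cpeptide(kin, knots, rates, bw, obs_t)
        rng = np.random.default_rng(12)
        noisy = obs * (1.0 + 0.03 * rng.standard_normal(len(obs)))
        cp = SampledSeries(obs_t, noisy, "c_peptide", "pmol/l")
        res = isr_deconvolve(cp, kin, DeconvConfig(residual_cv=0.03), bw=bw)
        grid = np.arange(0.0, 175.1, 1.0)
        est = np.trapezoid(np.interp(grid, res.times, res.isr), grid)
        tru = np.trapezoid(np.interp(grid, knots[:-1], rates), grid)
        assert abs(est - tru) / tru < 0.10

    def test_isr_never_negative(self, kin):
        rng = np.random.default_rng(5)
        t = np.arange(0.0, 180.1, 5.0)
        obs = 400 + 150 * np.sin(t / 25) + 30 * rng.standard_normal(len(t))
        cp = SampledSeries(t, np.maximum(obs, 10.0), "c_peptide", "pmol/l")
        res = isr_deconvolve(cp, kin, bw=78.0)
        assert np.all(res.isr >= 0.0)


class TestSensitivityIndex:
    def test_hand_value(self):
        # Rd/glucose in mg/ml gives a clearance, normalised per nmol/l
        assert insulin_sensitivity_index(1.85, 4.9, 32.1) == \
            pytest.approx(65.3, abs=0.05)

    def test_insulin_homogeneity(self):
        a = insulin_sensitivity_index(2.0, 5.0, 50.0)
        b = insulin_sensitivity_index(2.0, 5.0, 100.0)
        assert b == pytest.approx(a / 2.0)

    def test_zero_rd(self):
        assert insulin_sensitivity_index(0.0, 5.0, 50.0) == 0.0

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(EstimationError):
            insulin_sensitivity_index(1.0, 0.0, 50.0)


class TestTotalInsulinClearance:
    t = np.arange(0.0, 86.0, 5.0)

    def _pair(self, isr_level, ins_level):
        isr = SampledSeries(self.t, np.full_like(self.t, isr_level),
                            "isr", "pmol/kg/min")
        ins = SampledSeries(self.t, np.full_like(self.t, ins_level),
                            "insulin", "pmol/l")
        return isr, ins

    def test_hand_value(self):
        isr, ins = self._pair(5.0, 100.0)
        assert total_insulin_clearance(isr, ins, (0, 85)) == \
            pytest.approx(50.0, abs=1e-9)

    def test_zero_secretion(self):
        isr, ins = self._pair(0.0, 100.0)
        assert total_insulin_clearance(isr, ins, (0, 85)) == 0.0

    def test_scale_invariance(self):
        isr1, ins1 = self._pair(5.0, 100.0)
        isr2, ins2 = self._pair(10.0, 200.0)
        assert total_insulin_clearance(isr1, ins1, (0, 85)) == \
            pytest.approx(total_insulin_clearance(isr2, ins2, (0, 85)),
                          abs=1e-9)


class TestPosthepaticClearance:
    def test_steady_state_closed_form(self):
        t = np.arange(150.0, 171.0, 5.0)
        aspart = SampledSeries(t, np.full_like(t, 880.0), "aspart", "pmol/l")
        cl = posthepatic_clearance(aspart, 6.23, (150, 170))
        assert cl == pytest.approx(1000.0 * 6.23 / 880.0, abs=1e-9)

    def test_noise_free_linear_recovery(self):
        """Exact recovery when the data follow the one-compartment model
        with a piecewise-linear concentration course."""
        v, cl_true = 140.0, 7.0
        t = np.arange(150.0, 171.0, 5.0)
        i_obs = 800.0 + 2.0 * (t - 150.0)          # linear rise

        def rate(tt):
            tt = np.asarray(tt, float)
            i_t = 800.0 + 2.0 * (tt - 150.0)
            return (v * 2.0 + cl_true * i_t) / 1000.0

        aspart = SampledSeries(t, i_obs, "aspart", "pmol/l")
        cl = posthepatic_clearance(aspart, rate, (150, 170), v_ins=v)
        assert cl == pytest.approx(cl_true, abs=1e-6)

    def test_zero_concentration_not_identifiable(self):
        t = np.arange(150.0, 171.0, 5.0)
        aspart = SampledSeries(t, np.zeros_like(t), "aspart", "pmol/l")
        with pytest.raises(IdentifiabilityError):
            posthepatic_clearance(aspart, 6.23, (150, 170))


class TestHomaClassic:
    def test_hand_value(self):
        assert homa_classic(4.9, 32.1) == pytest.approx(1.165, abs=5e-4)

    def test_normalisation_point(self):
        assert homa_classic(22.5, 6.0) == pytest.approx(1.0, abs=1e-12)

    def test_zero_insulin(self):
        assert homa_classic(5.0, 0.0) == 0.0


class TestClearanceRecovery:
    def test_deconvolved_clearance_tracks_truth(self, recovery_cohort,
                                                protocol):
        """Across 50 simulated subjects, total insulin clearance from the
        deconvolved ISR is within 15% of the simulator's ground-truth
        post-hepatic endogenous clearance (median)."""
        errs = []
        for rec, truth in recovery_cohort[:50]:
            kin = CPeptideKinetics.population(
                age=rec.age, sex=rec.sex, height_cm=rec.height,
                weight_kg=rec.body_weight)
            res = isr_deconvolve(rec.channel("c_peptide"), kin,
                                 bw=rec.body_weight)
            cl_est = total_insulin_clearance(
                res.series(), rec.channel("insulin"),
                protocol.postprandial_window)
            p = truth.params
            cl_true = p.cl_ins / (1.0 - p.hepatic_extraction)
            errs.append(abs(cl_est / cl_true - 1.0))
        assert np.median(errs) <= 0.15
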