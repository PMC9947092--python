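"""Insulin secretion and clearance estimation.

The insulin secretion rate (ISR) is reconstructed from plasma C-peptide
by regularised deconvolution against two-compartment C-peptide kinetics
with population parameters (Van Cauter-type: short/long half-lives and
amplitude fraction mapped to rate constants, distribution volume scaled
to body surface area).  C-peptide is secreted equimolarly with insulin
and is not extracted by the liver, so the deconvolved rate is the
pre-hepatic secretion rate.

The deconvolution solves

    min  || C - H s ||^2  +  lambda || D2 s ||^2   s.t.  s >= 0

where H is the convolution matrix of the impulse response, s the ISR on
a uniform grid and D2 the second-difference operator.  lambda is chosen
by a discrepancy rule (residual RMS matched to the assay noise level)
unless fixed in the configuration.

Also here: the clamp's insulin sensitivity index (Rd adjusted for
glucose and insulin), total insulin clearance (AUC ISR / AUC insulin),
post-hepatic clearance from the insulin-analogue infusion via a linear
one-compartment model, and the classic HOMA-IR formula.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import lsq_linear

from .exceptions import EstimationError, IdentifiabilityError, ValidationError
from .records import SampledSeries
from .units import GLUCOSE_MMOL_L_TO_MG_ML


def dubois_bsa(height_cm: float, weight_kg: float) -> float:
    """DuBois body surface area, m^2."""
    return 0.007184 * height_cm ** 0.725 * weight_kg ** 0.425


@dataclass(frozen=True)
class CPeptideKinetics:
    """Two-compartment C-peptide kinetics.

    ``k01`` eliminates from the accessible compartment (volume ``V1`` in
    litres); ``k21``/``k12`` exchange with the peripheral compartment.
    The impulse response in the accessible compartment is a sum of two
    exponentials integrating to 1/(k01*V1).
    """

    k01: float = 0.0643
    k12: float = 0.0516
    k21: float = 0.0478
    v1: float = 4.9

    def __post_init__(self) -> None:
        if self.k01 <= 0 or self.v1 <= 0:
            raise ValidationError("k01 and v1 must be positive")
        if self.k12 < 0 or self.k21 < 0:
            raise ValidationError("k12 and k21 must be non-negative")

    # -- construction -----------------------------------------------------

    @classmethod
    def from_half_lives(cls, t_short: float, t_long: float,
                        fraction: float, v1: float) -> "CPeptideKinetics":
        """Rate constants from the bi-exponential decay parameters.

        ``fraction`` is the amplitude fraction of the short-half-life
        component.  Inverts C1(t)/C1(0) = f e^{-a t} + (1-f) e^{-b t}.
        """
        a = math.log(2.0) / t_short
        b = math.log(2.0) / t_long
        s1 = fraction * a + (1.0 - fraction) * b      # = k01 + k21
        k12 = a + b - s1
        k01 = a * b / k12
        k21 = s1 - k01
        return cls(k01=k01, k12=k12, k21=k21, v1=v1)

    @classmethod
    def population(cls, age: float = 45.0, sex: str = "F",
                   height_cm: float = 168.0, weight_kg: float = 78.0,
                   obese: bool = False) -> "CPeptideKinetics":
        """Population kinetics adjusted for body size.

        Half-lives 4.95/29.2 min with amplitude fraction 0.76 (4.55/26.5,
        0.78 when obese), distribution volume proportional to DuBois BSA
        (about 5 litres at BSA 1.86 m^2).  These are the standard
        population values used when C-peptide kinetics are not measured
        per subject.
        """
        if obese:
            t_short, t_long, frac = 4.55, 26.5, 0.78
        else:
            t_short, t_long, frac = 4.95, 29.2, 0.76
        v1 = 2.66 * dubois_bsa(height_cm, weight_kg)
        return cls.from_half_lives(t_short, t_long, frac, v1)

    # -- impulse response -------------------------------------------------

    def _eigen(self) -> tuple[float, float, float]:
        """(lam1, lam2, f): decay rates (lam1 >= lam2 >= 0) and the
        amplitude fraction of the fast component."""
        s = self.k01 + self.k12 + self.k21
        prod = self.k01 * self.k12
        disc = math.sqrt(max(0.0, s * s - 4.0 * prod))
        lam1 = 0.5 * (s + disc)
        lam2 = 0.5 * (s - disc)
        if lam1 == lam2:
            return lam1, lam2, 1.0
        f = (self.k01 + self.k21 - lam2) / (lam1 - lam2)
        return lam1, lam2, f

    def impulse_response(self, t) -> np.ndarray:
        """h(t): concentration in compartment 1 after a unit bolus.

        h(0) = 1/V1 and the integral to infinity is 1/(k01*V1).
        """
        t = np.asarray(t, dtype=float)
        lam1, lam2, f = self._eigen()
        h = (f * np.exp(-lam1 * t) + (1.0 - f) * np.exp(-lam2 * t)) / self.v1
        return np.where(t < 0, 0.0, h)

    def cumulative_response(self, t) -> np.ndarray:
        """Integral of the impulse response from 0 to t."""
        t = np.asarray(t, dtype=float)
        tc = np.maximum(t, 0.0)
        lam1, lam2, f = self._eigen()
        out = f * (1.0 - np.exp(-lam1 * tc)) / lam1
        if lam2 > 0:
            out = out + (1.0 - f) * (1.0 - np.exp(-lam2 * tc)) / lam2
        else:
            out = out + (1.0 - f) * tc
        return out / self.v1

    @property
    def steady_state_gain(self) -> float:
        """Plasma concentration per unit of sustained secretion rate:
        integral of h, i.e. 1/(k01*V1)."""
        return 1.0 / (self.k01 * self.v1)


def cpeptide_impulse_response(kin: CPeptideKinetics, t) -> np.ndarray:
    """Functional alias for :meth:`CPeptideKinetics.impulse_response`."""
    return kin.impulse_response(t)


@dataclass(frozen=True)
class DeconvConfig:
    """Deconvolution settings.

    ``lam`` fixes the regularisation weight; None selects it by the
    discrepancy rule targeting a residual RMS of ``residual_cv`` times
    the mean observed concentration (the assay's coefficient of
    variation).  ``step`` is the ISR discretisation interval in min.
    """

    lam: float | None = None
    residual_cv: float = 0.04
    step: float = 5.0
    nonneg: bool = True
    lam_grid: tuple[float, float, int] = (1e-4, 1e6, 21)

    def __post_init__(self) -> None:
        if self.lam is not None and self.lam < 0:
            raise ValidationError("lam must be >= 0")
        if self.step <= 0:
            raise ValidationError("step must be positive")


@dataclass
class ISRResult:
    """Deconvolved insulin secretion rate on a uniform grid."""

    times: np.ndarray          # interval start times, min
    isr: np.ndarray            # pmol/kg/min
    lam: float
    fitted: np.ndarray         # model C-peptide at the observation times
    residuals: np.ndarray

    def series(self) -> SampledSeries:
        """ISR as a sampled series (values stamped at interval starts)."""
        return SampledSeries(self.times, self.isr, "isr", "pmol/kg/min")


def _design_matrix(obs_times: np.ndarray, knots: np.ndarray,
                   kin: CPeptideKinetics, bw: float) -> np.ndarray:
    """Convolution matrix mapping piecewise-constant ISR (pmol/kg/min on
    [knots[j], knots[j+1])) to C-peptide (pmol/l) at the observation
    times.  Secretion before the first knot is assumed at the first
    interval's rate (steady pre-history)."""
    n, m = len(obs_times), len(knots) - 1
    A = np.zeros((n, m))
    for j in range(m):
        a, b = knots[j], knots[j + 1]
        A[:, j] = bw * (kin.cumulative_response(obs_times - a)
                        - kin.cumulative_response(obs_times - b))
    # steady pre-history folded into the first unknown
    A[:, 0] += bw * (kin.steady_state_gain
                     - kin.cumulative_response(obs_times - knots[0]))
    return A


def isr_deconvolve(cpeptide: SampledSeries, kin: CPeptideKinetics,
                   config: DeconvConfig | None = None,
                   bw: float = 78.0) -> ISRResult:
    """Reconstruct the insulin secretion rate from plasma C-peptide.

    Parameters
    ----------
    cpeptide : SampledSeries
        Plasma C-peptide, pmol/l, at least 6 samples.
    kin : CPeptideKinetics
    config : DeconvConfig
    bw : float
        Body weight, kg (the ISR is reported per kg).

    Returns
    -------
    ISRResult
        ISR in pmol/kg/min on intervals of ``config.step`` min.
    """
    config = config or DeconvConfig()
    c = np.asarray(cpeptide.values, dtype=float)
    t = np.asarray(cpeptide.times, dtype=float)
    if len(t) < 6:
        raise EstimationError("deconvolution needs at least 6 samples")
    if np.all(c == 0.0):
        knots = np.arange(t[0], t[-1] + config.step, config.step)
        m = len(knots) - 1
        return ISRResult(knots[:-1], np.zeros(m), 0.0,
                         np.zeros_like(c), np.zeros_like(c))

    n_int = int(np.ceil((t[-1] - t[0]) / config.step - 1e-9))
    knots = t[0] + config.step * np.arange(n_int + 1)
    A = _design_matrix(t, knots, kin, bw)
    m = A.shape[1]
    D2 = np.zeros((max(m - 2, 0), m))
    for i in range(m - 2):
        D2[i, i:i + 3] = (1.0, -2.0, 1.0)

    def solve(lam: float) -> tuple[np.ndarray, np.ndarray]:
        if D2.shape[0]:
            A_aug = np.vstack([A, math.sqrt(lam) * D2])
            b_aug = np.concatenate([c, np.zeros(D2.shape[0])])
        else:
            A_aug, b_aug = A, c
        if config.nonneg:
            sol = lsq_linear(A_aug, b_aug, bounds=(0.0, np.inf),
                             method="bvls", tol=1e-12)
            x = sol.x
        else:
            x, *_ = np.linalg.lstsq(A_aug, b_aug, rcond=None)
        return x, c - A @ x

    if config.lam is not None:
        x, resid = solve(config.lam)
        lam = config.lam
    else:
        # discrepancy rule: residual RMS ~ assay CV x mean level
        target = config.residual_cv * float(np.mean(np.abs(c)))
        lo, hi, n_lam = config.lam_grid
        best = None
        for lam_try in np.geomspace(lo, hi, int(n_lam)):
            x_try, r_try = solve(float(lam_try))
            rms = float(np.sqrt(np.mean(r_try ** 2)))
            score = abs(math.log((rms + 1e-30) / (target + 1e-30)))
            if best is None or score < best[0] - 1e-12:
                best = (score, float(lam_try), x_try, r_try)
        _, lam, x, resid = best
    return ISRResult(times=knots[:-1], isr=x, lam=lam,
                     fitted=c - resid, residuals=resid)


# ---------------------------------------------------------------------------
# sensitivity and clearance metrics
# ---------------------------------------------------------------------------

def insulin_sensitivity_index(rd: float, glucose: float,
                              insulin: float) -> float:
    """Rd adjusted for glucose and insulin: ml/min/kg per nmol/l.

    ``rd`` in mg/kg/min, ``glucose`` in mmol/l, ``insulin`` in pmol/l.
    Glucose converts to mg/ml so Rd/glucose is a clearance (ml/kg/min),
    then normalised by insulin in nmol/l.
    """
    if glucose <= 0 or insulin <= 0:
        raise EstimationError("glucose and insulin must be positive")
    clearance = rd / (glucose * GLUCOSE_MMOL_L_TO_MG_ML)   # ml/kg/min
    return clearance / (insulin / 1000.0)


def _series_mean(series: SampledSeries, window: tuple[float, float]) -> float:
    """Time-averaged value over a window (trapezoidal AUC / width)."""
    lo, hi = window
    sub = series.window(window)
    t = sub.times
    v = sub.values
    if len(t) == 0:
        raise EstimationError(
            f"{series.channel}: no samples in window [{lo}, {hi}]")
    if t[0] > lo and series.times[0] <= lo:
        t = np.insert(t, 0, lo)
        v = np.insert(v, 0, series.interp(lo))
    if t[-1] < hi and series.times[-1] >= hi:
        t = np.append(t, hi)
        v = np.append(v, series.interp(hi))
    if len(t) == 1:
        return float(v[0])
    return float(np.trapezoid(v, t) / (t[-1] - t[0]))


def insulin_sensitivity_window(rd: SampledSeries, glucose: SampledSeries,
                               insulins: list[SampledSeries],
                               window: tuple[float, float]) -> float:
    """Window version of the sensitivity index using time-averaged Rd,
    glucose and summed insulin (pass endogenous insulin alone for the
    postprandial window, endogenous + analogue for the hypoglycaemic
    window)."""
    rd_m = _series_mean(rd, window)
    g_m = _series_mean(glucose, window)
    i_m = sum(_series_mean(s, window) for s in insulins)
    return insulin_sensitivity_index(rd_m, g_m, i_m)


def total_insulin_clearance(isr: SampledSeries, insulin: SampledSeries,
                            window: tuple[float, float]) -> float:
    """AUC(ISR)/AUC(endogenous insulin) over a window, ml/kg/min.

    ISR in pmol/kg/min and insulin in pmol/l make the ratio l/kg/min;
    the factor 1000 reports ml/kg/min.
    """
    isr_mean = _series_mean(isr, window)
    ins_mean = _series_mean(insulin, window)
    if ins_mean <= 0:
        raise IdentifiabilityError("insulin AUC is zero in the window")
    return 1000.0 * isr_mean / ins_mean


def posthepatic_clearance(aspart: SampledSeries, infusion_rate,
                          window: tuple[float, float],
                          v_ins: float = 140.0,
                          fit_volume: bool = False):
    """Post-hepatic insulin clearance from the analogue infusion.

    Fits the linear one-compartment model V dI/dt = 1000 R(t) - CL I by
    least squares over the observation intervals inside ``window``
    (finite differences of observed I, trapezoidal integrals).  At steady
    state this reduces to CL = 1000 R / I_ss.

    Parameters
    ----------
    aspart : SampledSeries
        Plasma insulin analogue, pmol/l.
    infusion_rate : callable or float
        Infusion rate R(t) in pmol/kg/min (callable of time, or a
        constant).
    window : tuple
        Fit window, min; must contain at least 2 samples.
    v_ins : float
        Distribution volume, ml/kg (fixed unless ``fit_volume``).
    fit_volume : bool
        Also estimate V; returns (CL, V) in that case.

    Returns
    -------
    float or (float, float)
        CL in ml/kg/min (and V in ml/kg when fitted).
    """
    rate = infusion_rate if callable(infusion_rate) else (
        lambda t, _r=float(infusion_rate): np.full_like(np.asarray(t, float), _r))
    sub = aspart.window(window)
    t, i_obs = sub.times, sub.values
    if len(t) < 2:
        raise EstimationError("need at least 2 analogue samples in the window")
    if np.all(i_obs <= 0):
        raise IdentifiabilityError(
            "analogue concentration is zero throughout the window; "
            "clearance is not identifiable")
    a_int, di, r_int = [], [], []
    for k in range(len(t) - 1):
        tt = np.linspace(t[k], t[k + 1], 21)
        r_int.append(1000.0 * np.trapezoid(np.asarray(rate(tt), float), tt))
        ii = np.interp(tt, t, i_obs)
        a_int.append(np.trapezoid(ii, tt))
        di.append(i_obs[k + 1] - i_obs[k])
    a_int = np.asarray(a_int)
    di = np.asarray(di)
    r_int = np.asarray(r_int)
    if fit_volume:
        X = np.column_stack([a_int, di])
        beta, *_ = np.linalg.lstsq(X, r_int, rcond=None)
        return float(beta[0]), float(beta[1])
    denom = float(np.dot(a_int, a_int))
    if denom <= 0:
        raise IdentifiabilityError("insulin integral vanishes in the window")
    cl = float(np.dot(a_int, r_int - v_ins * di) / denom)
    return cl


def homa_classic(glucose_fasting: float, insulin_fasting: float) -> float:
    """Classic HOMA1-IR: G[mmol/l] * I[mU/l] / 22.5 with I converted
    from pmol/l (1 mU/l = 6 pmol/l).

    This is the textbook first-generation formula, not the structural
    HOMA2 computer model; the two agree only approximately (HOMA2 is
    calibrated so that normal insulin sensitivity gives %S near 100,
    and is nonlinear at high glucose/insulin).
    """
    if glucose_fasting <= 0:
        raise EstimationError("fasting glucose must be positive")
    if insulin_fasting < 0:
        raise EstimationError("fasting insulin must be non-negative")
    return glucose_fasting * (insulin_fasting / 6.0) / 22.5
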