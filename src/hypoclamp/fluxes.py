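"""Dual-tracer glucose-flux estimation (non-steady-state Steele).

Glucose turnover is estimated from plasma glucose and the two
tracer-to-tracee ratios: z1 for the continuously infused iv tracer
(rate F, mg/kg/min) and z2 for the label carried with the oral glucose.
With C the total plasma glucose concentration in mg/ml, p the pool
fraction and V the distribution volume (ml/kg), the single-pool
non-steady-state relations are

    Ra_tracee(t) = [ F - p V (C/(1+z1)) dz1/dt ] / z1
    Ra_tot(t)    = Ra_tracee(t) + F
    Rd(t)        = Ra_tot(t) - p V dC/dt
    C2(t)        = C z2 / (1 + z1 + z2)          (oral-tracer concentration)
    RaO(t)       = [ p V dC2/dt + Rd C2/C ] / e_oral
    EGP(t)       = Ra_tot - F - RaO - GIR

Ra_tot is reported inclusive of the iv tracer infusion (Ra_tracee + F):
at fasting steady state the total appearance then exceeds endogenous
production by exactly F, the convention under which the fasting flux
table's Ra_tot - EGP gap equals the infusion rate.

e_oral is the drink's label content; by the default ``mass_fraction``
convention the tracer flux is divided by the label mass fraction, giving
the total oral appearance including the label itself.  The ``ttr``
convention divides by the drink tracer-to-tracee ratio f/(1-f) and
yields the unlabelled oral appearance.

Derivatives are noise-amplifying, so the sampled series are smoothed
first: by default with a cubic smoothing spline whose penalty is chosen
by generalized cross-validation; a fixed-penalty spline (linear in the
data) and a local-polynomial smoother are available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import make_smoothing_spline

from .exceptions import EstimationError
from .io import require_channels
from .protocol import ProtocolConfig
from .records import SampledSeries, SubjectRecord
from .units import GLUCOSE_MMOL_L_TO_MG_ML


@dataclass(frozen=True)
class SteeleConfig:
    """Pool parameters and smoothing policy.

    p = 0.65 and V = 160 ml/kg are the conventional single-pool values
    for glucose in humans, where mixing is incomplete and the pool
    fraction discounts the effective volume for transients.  Against a
    perfectly mixed single-pool simulation the matched choice is p = 1
    with the simulator's volume.
    """

    pool_fraction: float = 0.65
    v_steele: float = 160.0
    smoother: str = "spline_gcv"     # spline_gcv | spline_fixed | local_poly
    lam: float = 50.0                # penalty for spline_fixed
    bandwidth: float = 45.0          # min, for local_poly
    gir_smooth: float = 11.0         # moving-average width (min) applied to
                                     # the GIR record before the partition
    log_enrichment: bool = True      # smooth the iv-tracer ratio in log
                                     # space (its washout is exponential,
                                     # near-linear in the log)
    oral_convention: str = "mass_fraction"   # mass_fraction | ttr

    def __post_init__(self) -> None:
        if not (0.0 < self.pool_fraction <= 1.0):
            raise EstimationError("pool_fraction must lie in (0, 1]")
        if self.v_steele <= 0:
            raise EstimationError("v_steele must be positive")
        if self.smoother not in ("spline_gcv", "spline_fixed", "local_poly"):
            raise EstimationError(f"unknown smoother {self.smoother!r}")
        if self.oral_convention not in ("mass_fraction", "ttr"):
            raise EstimationError(
                f"unknown oral_convention {self.oral_convention!r}")

    @property
    def pv(self) -> float:
        """Effective transient volume p*V, ml/kg."""
        return self.pool_fraction * self.v_steele


def default_grid(series: SampledSeries, step: float = 1.0) -> np.ndarray:
    lo = np.ceil(series.times[0] / step) * step
    hi = np.floor(series.times[-1] / step) * step
    return np.arange(lo, hi + step / 2, step)


def smooth_and_differentiate(series: SampledSeries, config: SteeleConfig,
                             grid: np.ndarray | None = None
                             ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Smoothed values and time derivatives on an analysis grid.

    Returns ``(grid, smoothed, derivative)``.  The fixed-penalty spline
    and the local-polynomial smoother are linear in the data; the
    GCV spline re-selects its penalty per series.  A constant series has
    zero derivative everywhere, and a sampled straight line is
    reproduced with its exact slope (lines are unpenalised).
    """
    if len(series) < 4:
        raise EstimationError(
            f"{series.channel}: need at least 4 samples to smooth, "
            f"got {len(series)}")
    grid = default_grid(series) if grid is None else np.asarray(grid, float)
    t, v = series.times, series.values
    if config.smoother in ("spline_gcv", "spline_fixed"):
        lam = None if config.smoother == "spline_gcv" else config.lam
        spl = make_smoothing_spline(t, v, lam=lam)
        return grid, spl(grid), spl.derivative()(grid)
    return _local_poly(t, v, grid, config.bandwidth)


def _local_poly(t: np.ndarray, v: np.ndarray, grid: np.ndarray,
                bandwidth: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Local quadratic regression with tricube weights."""
    sm = np.empty_like(grid)
    dv = np.empty_like(grid)
    for i, g in enumerate(grid):
        d = np.abs(t - g)
        h = bandwidth
        while np.sum(d <= h) < 4:   # widen until identifiable
            h *= 1.5
        w = np.clip(1.0 - (d / h) ** 3, 0.0, None) ** 3
        w[d > h] = 0.0
        mask = w > 0
        x = t[mask] - g
        W = np.diag(w[mask])
        Xd = np.column_stack([np.ones_like(x), x, x * x])
        A = Xd.T @ W @ Xd
        b = Xd.T @ W @ v[mask]
        try:
            beta = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:   # coincident support points
            beta = np.linalg.lstsq(A, b, rcond=None)[0]
        sm[i], dv[i] = beta[0], beta[1]
    return grid, sm, dv


def _smooth_enrichment(series: SampledSeries, config: SteeleConfig,
                       grid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Smoothed enrichment and its derivative.

    When ``log_enrichment`` is on and the samples are strictly positive,
    the smoother works on log values and transforms back (the iv
    tracer's washout is exponential, which a cubic spline represents
    poorly in linear space but almost exactly in log space); otherwise a
    plain fit.
    """
    if config.log_enrichment and np.all(series.values > 0):
        logged = SampledSeries(series.times, np.log(series.values),
                               series.channel, series.units)
        _, sm_log, d_log = smooth_and_differentiate(logged, config, grid)
        sm = np.exp(sm_log)
        return sm, sm * d_log
    _, sm, dv = smooth_and_differentiate(series, config, grid)
    return sm, dv


def steele_ratot(glucose: SampledSeries, z1: SampledSeries, F: float,
                 config: SteeleConfig | None = None,
                 grid: np.ndarray | None = None) -> SampledSeries:
    """Total glucose appearance Ra_tot (mg/kg/min) from the iv tracer.

    ``glucose`` in mmol/l, ``z1`` dimensionless, ``F`` in mg/kg/min.
    At steady state (both derivatives zero) the output equals the closed
    form F (1/z1 + 1) exactly.
    """
    config = config or SteeleConfig()
    if grid is None:
        lo = max(glucose.times[0], z1.times[0])
        hi = min(glucose.times[-1], z1.times[-1])
        grid = np.arange(np.ceil(lo), np.floor(hi) + 0.5, 1.0)
    _, g_sm, _ = smooth_and_differentiate(glucose, config, grid)
    z1_sm, dz1 = _smooth_enrichment(z1, config, grid)
    bad = np.nonzero(z1_sm <= 0)[0]
    if len(bad):
        raise EstimationError(
            f"smoothed z1 is non-positive at t={grid[bad[0]]:g} min")
    c = g_sm * GLUCOSE_MMOL_L_TO_MG_ML
    ra_tracee = (F - config.pv * (c / (1.0 + z1_sm)) * dz1) / z1_sm
    return SampledSeries(grid, ra_tracee + F, "ratot", "mg/kg/min")


def steele_rd(ratot: SampledSeries, glucose: SampledSeries,
              config: SteeleConfig | None = None) -> SampledSeries:
    """Glucose disappearance Rd = Ra_tot - p V dC/dt on Ra_tot's grid."""
    config = config or SteeleConfig()
    _, _, dg = smooth_and_differentiate(glucose, config, ratot.times)
    dc = dg * GLUCOSE_MMOL_L_TO_MG_ML
    return SampledSeries(ratot.times, ratot.values - config.pv * dc,
                         "rd", "mg/kg/min")


def oral_ra(glucose: SampledSeries, z1: SampledSeries, z2: SampledSeries,
            rd: SampledSeries, e_oral: float,
            config: SteeleConfig | None = None) -> SampledSeries:
    """Oral glucose appearance RaO (mg/kg/min) from the oral tracer.

    Computed on ``rd``'s grid.  Negative values are clipped to zero
    (diagnostic pre-clip values are the caller's concern via
    :func:`estimate_fluxes`); before the meal z2 = 0 gives RaO = 0.
    """
    config = config or SteeleConfig()
    if e_oral <= 0:
        raise EstimationError("e_oral must be positive")
    if np.any(z2.values < 0):
        raise EstimationError("z2 must be non-negative")
    grid = rd.times
    _, g_sm, _ = smooth_and_differentiate(glucose, config, grid)
    z1_sm, _ = _smooth_enrichment(z1, config, grid)
    _, z2_sm, _ = smooth_and_differentiate(z2, config, grid)
    z2_sm = np.maximum(z2_sm, 0.0)
    c = g_sm * GLUCOSE_MMOL_L_TO_MG_ML
    c2 = c * z2_sm / (1.0 + z1_sm + z2_sm)
    dc2 = np.gradient(c2, grid)
    denom = e_oral if config.oral_convention == "mass_fraction" \
        else e_oral / (1.0 - e_oral)
    rao = (config.pv * dc2 + rd.values * c2 / c) / denom
    return SampledSeries(grid, rao, "ra_o", "mg/kg/min")


def egp(ratot, rao, gir, F: float):
    """Endogenous glucose production by flux partition:
    EGP = Ra_tot - F - RaO - GIR.

    Accepts scalars or arrays on a shared grid; under fasting conditions
    (RaO = GIR = 0) this reduces to Ra_tot - F.
    """
    ratot_v = ratot.values if isinstance(ratot, SampledSeries) else ratot
    rao_v = rao.values if isinstance(rao, SampledSeries) else rao
    gir_v = gir.values if isinstance(gir, SampledSeries) else gir
    out = np.asarray(ratot_v, float) - F - np.asarray(rao_v, float) \
        - np.asarray(gir_v, float)
    if isinstance(ratot, SampledSeries):
        return SampledSeries(ratot.times, out, "egp", "mg/kg/min")
    return float(out) if np.ndim(out) == 0 else out


@dataclass
class FluxProfile:
    """Estimated fluxes on a shared analysis grid, mg/kg/min.

    Reported fluxes are clipped at zero; ``diagnostics`` keeps the
    pre-clip arrays, the smoothed inputs and the clipped-point fraction.
    """

    times: np.ndarray
    ratot: np.ndarray
    rd: np.ndarray
    ra_o: np.ndarray
    egp: np.ndarray
    diagnostics: dict = field(default_factory=dict)

    def series(self, name: str) -> SampledSeries:
        arr = {"ratot": self.ratot, "rd": self.rd, "ra_o": self.ra_o,
               "egp": self.egp}[name]
        return SampledSeries(self.times, arr, name, "mg/kg/min")

    def as_frame(self):
        import pandas as pd
        return pd.DataFrame({"time_min": self.times, "ratot": self.ratot,
                             "rd": self.rd, "ra_o": self.ra_o,
                             "egp": self.egp})


def _moving_average(values: np.ndarray, grid: np.ndarray,
                    width: float) -> np.ndarray:
    """Centred moving average on a uniform grid (edges renormalised)."""
    if width <= 0 or len(grid) < 2:
        return values
    step = grid[1] - grid[0]
    n = max(1, int(round(width / step)))
    if n % 2 == 0:
        n += 1
    kernel = np.ones(n) / n
    num = np.convolve(values, kernel, mode="same")
    den = np.convolve(np.ones_like(values), kernel, mode="same")
    return num / den


def _drop_isolated_background(series: SampledSeries,
                              max_gap: float = 30.0) -> SampledSeries:
    """Strip leading samples separated from the rest by more than
    ``max_gap`` min: background/calibration draws taken long before the
    kinetic sampling starts would otherwise bend the smoother across
    the gap."""
    t, v = series.times, series.values
    start = 0
    while start < len(t) - 1 and t[start + 1] - t[start] > max_gap:
        start += 1
    if start == 0:
        return series
    return SampledSeries(t[start:], v[start:], series.channel, series.units)


def estimate_fluxes(record: SubjectRecord, protocol: ProtocolConfig,
                    config: SteeleConfig | None = None) -> FluxProfile:
    """Full dual-tracer flux profile for one subject.

    Uses the glucose, z1, z2 and (when present) GIR channels; the GIR
    channel is reconstructed by zero-order hold since the infusion is
    piecewise constant between controller updates.  RaO is forced to
    zero before the meal.  Isolated background draws (taken right at
    tracer start, long before the basal sampling block) are excluded
    from the smoothing fits.
    """
    config = config or SteeleConfig()
    require_channels(record, ["glucose", "z1", "z2"], "flux estimation")
    glucose = _drop_isolated_background(record.channel("glucose"))
    z1 = _drop_isolated_background(record.channel("z1"))
    z2 = _drop_isolated_background(record.channel("z2"))
    lo = max(glucose.times[0], z1.times[0], z2.times[0])
    hi = min(glucose.times[-1], z1.times[-1], z2.times[-1])
    grid = np.arange(np.ceil(lo), np.floor(hi) + 0.5, 1.0)

    ratot = steele_ratot(glucose, z1, protocol.tracer_infusion, config, grid)
    rd = steele_rd(ratot, glucose, config)
    rao = oral_ra(glucose, z1, z2, rd, protocol.oral_label_fraction, config)
    rao_raw = rao.values.copy()
    rao_clipped = np.clip(rao_raw, 0.0, None)
    rao_clipped[grid < 0] = 0.0

    if record.has_channel("gir"):
        gs = record.channel("gir")
        idx = np.clip(np.searchsorted(gs.times, grid, side="right") - 1,
                      0, len(gs.times) - 1)
        gir_vals = gs.values[idx]
        gir_vals[grid < gs.times[0]] = 0.0
    else:
        gir_vals = np.zeros_like(grid)

    # the smoothed-derivative fluxes cannot track the controller's
    # square-wave infusion, so the partition uses a GIR averaged to the
    # estimator's bandwidth; the raw reconstruction stays in diagnostics
    gir_for_partition = _moving_average(gir_vals, grid, config.gir_smooth)
    egp_raw = (ratot.values - protocol.tracer_infusion - rao_clipped
               - gir_for_partition)
    ratot_raw = ratot.values.copy()
    rd_raw = rd.values.copy()
    n_neg = sum(int(np.sum(a < 0)) for a in (ratot_raw, rd_raw, rao_raw, egp_raw))
    profile = FluxProfile(
        times=grid,
        ratot=np.clip(ratot_raw, 0.0, None),
        rd=np.clip(rd_raw, 0.0, None),
        ra_o=rao_clipped,
        egp=np.clip(egp_raw, 0.0, None),
        diagnostics={
            "ratot_raw": ratot_raw, "rd_raw": rd_raw, "rao_raw": rao_raw,
            "egp_raw": egp_raw, "gir": gir_vals,
            "gir_smoothed": gir_for_partition,
            "clipped_fraction": n_neg / (4.0 * len(grid)),
        })
    return profile


def fasting_flux_metrics(profile: FluxProfile,
                         window: tuple[float, float] = (-30.0, -15.0)
                         ) -> dict[str, float]:
    """Fasting fluxes as time-averages over a pre-meal window.

    The window deliberately ends well before the meal: a smoothing
    spline cannot represent the derivative kink at ingestion and its
    fit oscillates for about one sampling interval on either side of
    the kink, so the fasting estimate is taken clear of that boundary.
    """
    t = profile.times
    m = (t >= window[0]) & (t <= window[1])
    if not np.any(m):
        raise EstimationError(f"profile does not cover {window}")
    return {"fasting_ratot": float(np.mean(profile.ratot[m])),
            "fasting_rd": float(np.mean(profile.rd[m])),
            "fasting_egp": float(np.mean(profile.egp[m]))}


def postprandial_flux_metrics(profile: FluxProfile, protocol: ProtocolConfig,
                              bw: float) -> dict[str, float]:
    """Early-postprandial flux summaries.

    AUCs over the first 15 min of RaO, Ra_tot and Rd (trapezoidal, on
    the analysis grid); EGP suppression at t15 as the relative
    difference to t0 (negative = suppression); and the oral-glucose
    recovery over the postprandial window as a percentage of the load.
    """
    t = profile.times
    lo, hi = protocol.postprandial_window
    if t[0] > lo or t[-1] < hi:
        raise EstimationError(
            f"profile [{t[0]:g}, {t[-1]:g}] does not cover the "
            f"postprandial window [{lo:g}, {hi:g}]")

    def _auc(arr, a, b):
        m = (t >= a) & (t <= b)
        return float(np.trapezoid(arr[m], t[m]))

    egp0 = float(np.interp(0.0, t, profile.egp))
    egp15 = float(np.interp(15.0, t, profile.egp))
    if egp0 == 0:
        raise EstimationError("EGP at t0 is zero; suppression undefined")
    return {
        "auc0_15_rao": _auc(profile.ra_o, 0.0, 15.0),
        "auc0_15_ratot": _auc(profile.ratot, 0.0, 15.0),
        "auc0_15_rd": _auc(profile.rd, 0.0, 15.0),
        "egp_suppression_t15": (egp15 - egp0) / egp0,
        "recovery_percent": _auc(profile.ra_o, lo, hi) * bw
        / protocol.oral_dose * 100.0,
    }
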