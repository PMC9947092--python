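"""Reference glycaemic trajectory and discrete PID control of the GIR.

During the clamp the insulin infusion pulls glucose down while the
controller modulates the exogenous glucose infusion rate (GIR, the only
actuation variable) to keep measured glucose on a reference trajectory:
a standardised descent from the level at insulin start to the 2.5 mmol/l
target at t150, a 20-min hold, then restoration towards euglycaemia.

The controller is a textbook positional PID with output clipping to
[0, GIR_max] and conditional-integration anti-windup: the integral
accumulator is frozen whenever the output saturates in the direction the
error would push it further.  It is a pure function of its inputs — no
hidden state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .exceptions import ValidationError
from .protocol import ProtocolConfig
from .records import SampledSeries


@dataclass(frozen=True)
class ControllerConfig:
    """PID gains and actuation limits.

    Gains are in GIR units (mg/kg/min) per mmol/l (Kp), per mmol/l*min
    (Ki) and per mmol/l/min (Kd).  ``anti_windup`` bounds the integral
    accumulator (mmol/l*min).  The descent reference is linear by
    default; an exponential shape (fast early drop, soft landing on the
    target) is available via ``descent_shape``.
    """

    kp: float = 6.0
    ki: float = 1.0
    kd: float = 12.0
    update_interval: float = 5.0
    gir_max: float = 15.0
    anti_windup: float = 25.0
    restoration_target: float = 5.0
    restoration_duration: float = 30.0
    descent_shape: str = "linear"      # "linear" | "exponential"
    descent_rate: float = 3.0          # shape constant of the exponential descent

    def __post_init__(self) -> None:
        if min(self.kp, self.ki, self.kd) < 0:
            raise ValidationError("PID gains must be non-negative")
        if self.update_interval <= 0:
            raise ValidationError("update_interval must be positive")
        if self.gir_max <= 0:
            raise ValidationError("gir_max must be positive")
        if self.descent_shape not in ("linear", "exponential"):
            raise ValidationError(f"unknown descent_shape {self.descent_shape!r}")


@dataclass(frozen=True)
class ControllerState:
    """Discrete controller state between updates."""

    integral: float = 0.0
    prev_error: float | None = None
    prev_gir: float = 0.0
    phase: str = "pre_insulin"   # pre_insulin | descent | hold | restoration


def reference_trajectory(protocol: ProtocolConfig,
                         g_at_insulin_start: float,
                         config: ControllerConfig | None = None) -> SampledSeries:
    """Reference glucose trajectory on the controller grid.

    Piecewise: descent from (insulin_start, G0) to (hypo start, target);
    constant target over the hypoglycaemic window; linear restoration to
    ``restoration_target`` over ``restoration_duration``.
    """
    config = config or ControllerConfig()
    target = protocol.hypo_target
    if g_at_insulin_start <= target:
        raise ValidationError(
            f"glucose at insulin start ({g_at_insulin_start:g} mmol/l) must "
            f"exceed the hypoglycaemic target ({target:g} mmol/l)")
    t0, (t_lo, t_hi) = protocol.insulin_start, protocol.hypo_window
    t_end = t_hi + config.restoration_duration
    n = int(round((t_end - t0) / config.update_interval))
    times = t0 + config.update_interval * np.arange(n + 1)
    values = np.empty_like(times)
    for i, t in enumerate(times):
        if t <= t_lo:
            frac = (t - t0) / (t_lo - t0)
            if config.descent_shape == "linear":
                values[i] = g_at_insulin_start + frac * (target - g_at_insulin_start)
            else:
                a = config.descent_rate
                w = (math.exp(-a * frac) - math.exp(-a)) / (1.0 - math.exp(-a))
                values[i] = target + (g_at_insulin_start - target) * w
        elif t <= t_hi:
            values[i] = target
        else:
            frac = min(1.0, (t - t_hi) / config.restoration_duration)
            values[i] = target + frac * (config.restoration_target - target)
    return SampledSeries(times, values, "glucose", "mmol/l")


def pid_step(state: ControllerState, g_measured: float, g_ref: float,
             config: ControllerConfig, dt: float) -> tuple[float, ControllerState]:
    """One discrete PID update.

    Error convention: e = reference - measurement, so glucose below the
    reference yields a positive error and hence glucose infusion; glucose
    above the reference clips the output at zero (the controller cannot
    remove glucose).
    """
    if dt <= 0:
        raise ValidationError("dt must be positive")
    e = g_ref - g_measured
    deriv = 0.0 if state.prev_error is None else (e - state.prev_error) / dt
    integral_cand = float(np.clip(state.integral + e * dt,
                                  -config.anti_windup, config.anti_windup))
    u = config.kp * e + config.ki * integral_cand + config.kd * deriv
    gir = float(np.clip(u, 0.0, config.gir_max))
    saturated_high = u > config.gir_max and e > 0
    saturated_low = u < 0.0 and e < 0
    integral = state.integral if (saturated_high or saturated_low) else integral_cand
    new_state = ControllerState(integral=integral, prev_error=e,
                                prev_gir=gir, phase=state.phase)
    return gir, new_state


def run_closed_loop(step, g0: float, config: ControllerConfig,
                    protocol: ProtocolConfig, t_end: float | None = None):
    """Run the clamp loop against a subject-dynamics callable.

    Parameters
    ----------
    step : callable
        ``step(gir, t_start, t_stop) -> float`` advances the subject's
        state under a constant GIR over one update interval and returns
        the measured glucose at ``t_stop``.
    g0 : float
        Measured glucose at insulin start (anchors the reference).
    config, protocol
        Controller and protocol configuration.
    t_end : float, optional
        Loop end; defaults to the end of the restoration ramp.

    Returns
    -------
    (gir_series, glucose_series, states, achieved_window)
        GIR is piecewise constant over update intervals (value stamped at
        the interval start); glucose is the measurement at each update;
        ``achieved_window`` is the 20-min window starting when measured
        glucose first came within 0.1 mmol/l of the target (nominal
        window if that happens on schedule).
    """
    ref = reference_trajectory(protocol, g0, config)
    if t_end is None:
        t_end = float(ref.times[-1])
    dt = config.update_interval
    t = protocol.insulin_start
    g = g0
    state = ControllerState(phase="descent")
    times, girs, glucoses, states = [t], [], [g], [state]
    while t < t_end - 1e-9:
        g_ref = float(np.interp(t, ref.times, ref.values))
        gir, state = pid_step(state, g, g_ref, config, dt)
        g = step(gir, t, t + dt)
        t += dt
        times.append(t)
        girs.append(gir)
        glucoses.append(g)
        states.append(state)
    times = np.asarray(times)
    glucose_series = SampledSeries(times, np.asarray(glucoses),
                                   "glucose", "mmol/l")
    # GIR stamped at interval starts; final sample repeats the last rate
    gir_series = SampledSeries(times, np.asarray(girs + [girs[-1]]),
                               "gir", "mg/kg/min")
    tol = 0.1
    at_target = np.nonzero(np.asarray(glucoses)
                           <= protocol.hypo_target + tol)[0]
    if len(at_target) > 0:
        start = max(protocol.hypo_window[0], float(times[at_target[0] + 1]))
    else:
        start = protocol.hypo_window[0]
    achieved = (start, start + protocol.hypo_duration)
    return gir_series, glucose_series, states, achieved
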