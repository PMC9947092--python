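"""Virtual-subject simulator for the postprandial hypoglycaemic clamp.

A deterministic ODE model of glucose-insulin-tracer-hormone dynamics in
the oral-minimal-model style: a single well-mixed glucose pool, a
two-compartment gut (stomach -> gut -> absorption), remote insulin
action, threshold-linear insulin secretion, two-compartment C-peptide
kinetics, one-compartment endogenous-insulin and insulin-analogue
pharmacokinetics, both glucose tracers (the infused iv tracer and the
oral label carried with the drink), and first-order counter-regulatory
hormone responses activated below per-hormone glucose thresholds.
Counter-regulation feeds back on endogenous glucose production as a
threshold-linear term, so the ground-truth EGP stays interpretable.

State equations (per kg of body weight where applicable, time in min):

    dq_sto/dt = ingestion(t) - k_empt q_sto            [mg]
    dq_gut/dt = k_empt q_sto - k_abs q_gut             [mg]
    RaO       = f_bio k_abs q_gut / BW                 [mg/kg/min]
    dX/dt     = -p2 (X - S_I (I_tot - I_b))            [1/min]
    EGP       = max(0, EGP_b (1 - k_X X)
                    + gamma_CR max(0, G_CR - G))       [mg/kg/min]
    Rd        = (S_G + X) G V_g 0.18016                [mg/kg/min]
    dG/dt     = (EGP + RaO + GIR + F - Rd)/(V_g 0.18016)
    dc1/dt    = F/V_g - k_d c1,   k_d = S_G + X        [mg/ml]
    dc2/dt    = e_oral RaO / V_g - k_d c2              [mg/ml]
    ISR       = max(0, ISR_b + beta (G - G_thr))       [pmol/kg/min]
    hormones  dh/dt = (basal + gain max(0, thr - G) - h)/tau

The tracer-to-tracee ratios reported to the estimators are
z_i = c_i / (C_tot - c1 - c2) with C_tot = G * 0.18016 mg/ml.

The generator's defaults are calibration choices producing the study's
protocol conditions (glucose reaching 2.5 mmol/l at t150, oral recovery
in the low-60% range, fasting turnover near 1.85 mg/kg/min, clamped
insulin-analogue levels near 900 pmol/l); they are not fitted to any
individual human dataset.  Group templates perturb them to produce the
qualitative group contrasts (faster gastric emptying and brisker
secretion after gastric bypass, blunted glucagon in all surgical groups,
near-absent pancreatic-polypeptide response in the hypoglycaemia-prone
group).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from ._version import __version__ as _pkg_version
from .controller import ControllerConfig, run_closed_loop
from .exceptions import SimulationError, ValidationError
from .protocol import (CHANNEL_UNITS, SYMPTOM_ITEMS_AUTONOMIC,
                       SYMPTOM_ITEMS_NEUROGLYCOPENIC, ProtocolConfig)
from .records import CohortDataset, SampledSeries, SubjectRecord
from .secretion import CPeptideKinetics
from .units import GLUCOSE_MMOL_L_TO_MG_ML

HORMONES = ("glucagon", "adrenaline", "noradrenaline", "cortisol", "gh", "pp")


@dataclass(frozen=True)
class SubjectParams:
    """Mechanistic parameters of one virtual subject.

    Defaults describe an insulin-sensitive non-surgical adult.  ``s_g``
    defaults to the value that makes the fasting state an exact steady
    state of the model (disposal balancing basal production plus the
    tracer infusion at basal glucose).
    """

    bw: float = 78.0                  # body weight, kg
    g_b: float = 4.9                  # basal glucose, mmol/l
    v_g: float = 160.0                # glucose distribution volume, ml/kg
    egp_b: float = 1.82               # basal EGP, mg/kg/min
    s_g: float | None = None          # glucose effectiveness, 1/min
    s_i: float = 3.5e-5               # insulin sensitivity, 1/min per pmol/l
    p2: float = 0.05                  # insulin-action rate, 1/min
    k_x: float = 22.0                 # EGP inhibition per unit X, min
    k_empt: float = 0.045             # gastric emptying, 1/min
    k_abs: float = 0.06               # intestinal absorption, 1/min
    f_bio: float = 0.68               # systemic oral bioavailability (net of first-pass splanchnic uptake)
    basal_isr: float = 1.5            # fasting secretion, pmol/kg/min
    beta_sec: float = 2.4             # secretion slope, pmol/kg/min per mmol/l
    g_sec_thr: float | None = None    # secretion threshold, mmol/l (basal G)
    hepatic_extraction: float = 0.5   # first-pass insulin extraction
    cl_ins: float = 23.4              # endogenous insulin clearance, ml/kg/min
    cl_aspart: float = 7.08           # analogue clearance, ml/kg/min
    v_ins: float = 140.0              # insulin distribution volume, ml/kg
    hr_basal: float = 70.0            # heart rate baseline, bpm
    hr_gain: float = 14.0             # bpm per mmol/l below 3.5
    bp_sys: float = 121.0             # systolic BP, mmHg
    bp_dia: float = 78.0              # diastolic BP baseline, mmHg
    bp_dia_drop: float = 6.0          # diastolic drop per mmol/l below 3.5
    glp1_b: float = 1.7               # fasting GLP-1, pmol/l
    glp1_amp: float = 3.0             # GLP-1 rise per mg/kg/min of RaO
    age: float = 45.0
    sex: str = "F"
    height: float = 168.0
    cpeptide: CPeptideKinetics | None = None

    def __post_init__(self) -> None:
        for name in ("bw", "g_b", "egp_b", "s_i", "p2", "k_empt", "k_abs",
                     "basal_isr", "beta_sec", "cl_ins", "cl_aspart", "v_ins"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if not (0.0 <= self.f_bio <= 1.0):
            raise ValidationError("f_bio must lie in [0, 1]")
        if not (0.0 <= self.hepatic_extraction <= 1.0):
            raise ValidationError("hepatic_extraction must lie in [0, 1]")
        if not (100.0 <= self.v_g <= 300.0):
            raise ValidationError("v_g must lie in [100, 300] ml/kg")

    def resolved(self, protocol: ProtocolConfig) -> "SubjectParams":
        """Fill derived defaults (steady-state s_g, secretion threshold,
        population C-peptide kinetics)."""
        s_g = self.s_g
        if s_g is None:
            # fasting balance: (S_G)*G_b*V_g*0.18016 = EGP_b + F
            s_g = ((self.egp_b + protocol.tracer_infusion)
                   / (self.g_b * self.v_g * GLUCOSE_MMOL_L_TO_MG_ML))
        g_thr = self.g_b if self.g_sec_thr is None else self.g_sec_thr
        kin = self.cpeptide or CPeptideKinetics.population(
            age=self.age, sex=self.sex, height_cm=self.height,
            weight_kg=self.bw)
        return replace(self, s_g=s_g, g_sec_thr=g_thr, cpeptide=kin)

    @property
    def i_basal(self) -> float:
        """Fasting endogenous insulin, pmol/l (post-hepatic balance)."""
        return (1.0 - self.hepatic_extraction) * self.basal_isr * 1000.0 / self.cl_ins


@dataclass(frozen=True)
class HormoneResponse:
    """First-order counter-regulatory response of one hormone."""

    basal: float
    gain: float      # response amplitude per mmol/l below threshold
    g_thr: float     # activation threshold, mmol/l
    tau: float       # response time constant, min

    def __post_init__(self) -> None:
        if self.basal < 0 or self.gain < 0:
            raise ValidationError("basal and gain must be >= 0")
        if self.tau <= 0:
            raise ValidationError("tau must be positive")


def _default_hormones() -> dict[str, HormoneResponse]:
    return {
        "glucagon": HormoneResponse(4.9, 18.0, 3.8, 15.0),       # pmol/l
        "adrenaline": HormoneResponse(0.10, 1.2, 3.5, 15.0),     # nmol/l
        "noradrenaline": HormoneResponse(2.0, 1.0, 3.4, 20.0),   # nmol/l
        "cortisol": HormoneResponse(198.0, 160.0, 3.2, 30.0),    # nmol/l
        "gh": HormoneResponse(0.2, 6.0, 3.4, 25.0),              # ug/l
        "pp": HormoneResponse(9.9, 230.0, 3.5, 15.0),            # pmol/l
    }


@dataclass(frozen=True)
class HormoneParams:
    """Counter-regulatory hormone responses plus the EGP coupling.

    ``gamma_cr`` converts glucose depth below ``g_thr_cr`` into extra
    endogenous glucose production (mg/kg/min per mmol/l), standing in
    for the aggregate hepatic effect of the hormones.
    """

    responses: dict[str, HormoneResponse] = field(default_factory=_default_hormones)
    gamma_cr: float = 0.30
    g_thr_cr: float = 3.5

    def __post_init__(self) -> None:
        missing = set(HORMONES) - set(self.responses)
        if missing:
            raise ValidationError(f"missing hormone responses: {sorted(missing)}")
        if self.gamma_cr < 0:
            raise ValidationError("gamma_cr must be >= 0")

    def scaled(self, gain_multipliers: dict[str, float]) -> "HormoneParams":
        resp = dict(self.responses)
        for name, mult in gain_multipliers.items():
            r = resp[name]
            resp[name] = replace(r, gain=r.gain * mult)
        return replace(self, responses=resp)


_DEFAULT_NOISE_CV = {"glucose": 0.02, "z1": 0.015, "z2": 0.015,
                     "heart_rate": 0.03, "bp_systolic": 0.03,
                     "bp_dia": 0.03}


@dataclass(frozen=True)
class GroupTemplate:
    """Parameter multipliers and noise levels defining a study group.

    Multipliers act on :class:`SubjectParams` fields (by name) and on
    hormone response gains; they are calibration knobs chosen to
    reproduce the qualitative group contrasts, not fitted quantities.
    Measurement noise is multiplicative Gaussian with per-channel CV
    (defaults: glucose 2%, enrichments 1.5%, hormones 5%).
    """

    name: str
    param_multipliers: dict[str, float] = field(default_factory=dict)
    hormone_multipliers: dict[str, float] = field(default_factory=dict)
    symptom_intensity: float = 1.0
    noise_cv: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for k, v in {**self.param_multipliers, **self.hormone_multipliers}.items():
            if v <= 0:
                raise ValidationError(f"multiplier {k} must be positive")
        for k, v in self.noise_cv.items():
            if not (0.0 <= v <= 0.2):
                raise ValidationError(f"noise CV {k} must lie in [0, 0.2]")

    def cv_for(self, channel: str) -> float:
        if channel in self.noise_cv:
            return self.noise_cv[channel]
        if channel in _DEFAULT_NOISE_CV:
            return _DEFAULT_NOISE_CV[channel]
        if channel == "gir" or channel.startswith("symptom_"):
            return 0.0
        if channel.startswith("bp_"):
            return 0.03
        return 0.05   # hormones and peptides


def default_templates() -> dict[str, GroupTemplate]:
    """The four study groups.

    Gastric-bypass anatomy (PBH, RYGB) accelerates gastric emptying and
    steepens the secretion response; all surgical groups have a blunted
    glucagon gain; the PBH group has the weakest pancreatic-polypeptide
    response; analogue clearance multipliers spread the clamped analogue
    levels across groups.
    """
    return {
        "PBH": GroupTemplate(
            "PBH",
            param_multipliers={"k_empt": 1.8, "beta_sec": 1.6,
                               "cl_aspart": 0.95},
            hormone_multipliers={"glucagon": 0.40, "pp": 0.10},
            symptom_intensity=1.3),
        "RYGB": GroupTemplate(
            "RYGB",
            param_multipliers={"k_empt": 1.8, "beta_sec": 1.8,
                               "cl_aspart": 1.70},
            hormone_multipliers={"glucagon": 0.40, "pp": 0.50}),
        "SG": GroupTemplate(
            "SG",
            param_multipliers={"k_empt": 1.3, "beta_sec": 1.2,
                               "cl_aspart": 0.85},
            hormone_multipliers={"glucagon": 0.40, "pp": 0.50}),
        "CN": GroupTemplate("CN"),
    }


@dataclass
class TruthRecord:
    """Simulator ground truth on the fine (1-min) grid."""

    times: np.ndarray
    ra_o: np.ndarray          # mg/kg/min
    egp: np.ndarray
    rd: np.ndarray
    ra_tot: np.ndarray        # EGP + RaO + GIR + F
    gir: np.ndarray
    isr: np.ndarray           # pmol/kg/min
    channels: dict[str, np.ndarray]   # noise-free channel trajectories
    params: SubjectParams
    achieved_window: tuple[float, float]

    def flux(self, name: str) -> SampledSeries:
        arr = {"ra_o": self.ra_o, "egp": self.egp, "rd": self.rd,
               "ra_tot": self.ra_tot, "gir": self.gir, "isr": self.isr}[name]
        units = "pmol/kg/min" if name == "isr" else "mg/kg/min"
        return SampledSeries(self.times, arr, name, units)


# state vector layout
_NSTATE = 16
(_Q_STO, _Q_GUT, _G, _X, _C1, _C2, _QCP1, _QCP2, _I_END, _I_ASP,
 _H0) = 0, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10


class _Model:
    """RHS and bookkeeping for one subject's simulation."""

    def __init__(self, p: SubjectParams, h: HormoneParams,
                 protocol: ProtocolConfig, meal: bool, insulin: bool):
        self.p = p
        self.h = h
        self.proto = protocol
        self.meal = meal
        self.insulin = insulin
        self.vg_mg = p.v_g * GLUCOSE_MMOL_L_TO_MG_ML   # mg/kg per mmol/l
        self.i_b = p.i_basal
        self.resp = [h.responses[name] for name in HORMONES]

    def initial_state(self) -> np.ndarray:
        p = self.p
        y = np.zeros(_NSTATE)
        # the prime enters the tracer balance only: 3 mg/kg is ~0.1% of
        # pool glucose mass and is neglected in the cold glucose balance
        y[_G] = p.g_b
        y[_C1] = self.proto.prime_dose / p.v_g
        kin = p.cpeptide
        q1 = p.basal_isr * p.bw / kin.k01
        y[_QCP1] = q1
        y[_QCP2] = kin.k21 * q1 / kin.k12 if kin.k12 > 0 else 0.0
        y[_I_END] = self.i_b
        for i, r in enumerate(self.resp):
            y[_H0 + i] = r.basal
        return y

    def ingestion(self, t: float) -> float:
        if not self.meal:
            return 0.0
        if 0.0 <= t < self.proto.ingestion_duration:
            return self.proto.oral_dose / self.proto.ingestion_duration
        return 0.0

    def aspart_rate(self, t: float) -> float:
        if not self.insulin:
            return 0.0
        if self.proto.insulin_start <= t < self.proto.hypo_window[1]:
            return self.proto.insulin_rate_pmol_kg_min
        return 0.0

    def fluxes(self, t: float, y: np.ndarray) -> tuple[float, float, float, float]:
        """(RaO, EGP, Rd, ISR) at a state."""
        p = self.p
        ra_o = p.f_bio * p.k_abs * y[_Q_GUT] / p.bw
        g = y[_G]
        egp = max(0.0, p.egp_b * (1.0 - p.k_x * y[_X])
                  + self.h.gamma_cr * max(0.0, self.h.g_thr_cr - g))
        rd = (p.s_g + y[_X]) * g * self.vg_mg
        isr = max(0.0, p.basal_isr + p.beta_sec * (g - p.g_sec_thr))
        return ra_o, egp, rd, isr

    def rhs(self, t: float, y: np.ndarray, gir: float) -> np.ndarray:
        p = self.p
        kin = p.cpeptide
        ra_o, egp, rd, isr = self.fluxes(t, y)
        g = y[_G]
        kd = p.s_g + y[_X]
        dy = np.empty(_NSTATE)
        dy[_Q_STO] = self.ingestion(t) - p.k_empt * y[_Q_STO]
        dy[_Q_GUT] = p.k_empt * y[_Q_STO] - p.k_abs * y[_Q_GUT]
        dy[_G] = (egp + ra_o + gir + self.proto.tracer_infusion - rd) / self.vg_mg
        i_tot = y[_I_END] + y[_I_ASP]
        dy[_X] = -p.p2 * (y[_X] - p.s_i * (i_tot - self.i_b))
        dy[_C1] = self.proto.tracer_infusion / p.v_g - kd * y[_C1]
        dy[_C2] = (self.proto.oral_label_fraction * ra_o / p.v_g
                   - kd * y[_C2])
        dy[_QCP1] = (isr * p.bw - (kin.k01 + kin.k21) * y[_QCP1]
                     + kin.k12 * y[_QCP2])
        dy[_QCP2] = kin.k21 * y[_QCP1] - kin.k12 * y[_QCP2]
        dy[_I_END] = ((1.0 - p.hepatic_extraction) * isr * 1000.0
                      - p.cl_ins * y[_I_END]) / p.v_ins
        dy[_I_ASP] = (self.aspart_rate(t) * 1000.0
                      - p.cl_aspart * y[_I_ASP]) / p.v_ins
        for i, r in enumerate(self.resp):
            drive = r.basal + r.gain * max(0.0, r.g_thr - g)
            dy[_H0 + i] = (drive - y[_H0 + i]) / r.tau
        return dy


def _rk4(model: _Model, y: np.ndarray, t0: float, t1: float, gir: float,
         dt: float, record) -> np.ndarray:
    """Fixed-step RK4 from t0 to t1 under constant GIR; calls
    ``record(t, y, gir)`` at every whole-minute node (including t1 when
    integral)."""
    n = int(round((t1 - t0) / dt))
    t = t0
    for _ in range(n):
        k1 = model.rhs(t, y, gir)
        k2 = model.rhs(t + dt / 2, y + dt / 2 * k1, gir)
        k3 = model.rhs(t + dt / 2, y + dt / 2 * k2, gir)
        k4 = model.rhs(t + dt, y + dt * k3, gir)
        y = y + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        t = t0 + (_ + 1) * dt   # avoid accumulated rounding
        if y[_G] <= 0.5:
            raise SimulationError(
                f"glucose fell to {y[_G]:.2f} mmol/l at t={t:.1f} min "
                f"(params: s_i={model.p.s_i:g}, cl_aspart={model.p.cl_aspart:g})")
        if abs(round(t) - t) < 1e-9:
            record(round(t), y, gir)
    return y


def simulate_subject(params: SubjectParams | None = None,
                     hormones: HormoneParams | None = None,
                     protocol: ProtocolConfig | None = None,
                     controller: ControllerConfig | None = None,
                     seed=0,
                     template: GroupTemplate | None = None,
                     subject_id: str = "S1",
                     group: str = "CN",
                     meal: bool = True,
                     insulin: bool = True,
                     noise: bool = False,
                     sim_end: float = 200.0,
                     fine_dt: float = 0.25) -> tuple[SubjectRecord, TruthRecord]:
    """Simulate one subject through the clamp protocol.

    Parameters
    ----------
    params, hormones, protocol
        Model configuration; defaults describe the reference non-surgical
        subject under the study protocol.
    controller
        PID configuration for the closed-loop GIR; None runs open loop
        with GIR = 0 throughout.
    seed
        Seed (int or numpy SeedSequence) for measurement noise and the
        symptom ratings.
    template
        Supplies per-channel noise CVs and symptom intensity; defaults to
        the plain CN template.
    meal, insulin
        Disable the oral load or the insulin phase (for steady-state and
        open-loop checks).
    noise
        Apply multiplicative Gaussian measurement noise (truncated at
        zero) when sampling channels.

    Returns
    -------
    (SubjectRecord, TruthRecord)
        The sampled record on the protocol grids and the fine-grid
        ground truth.
    """
    protocol = protocol or ProtocolConfig()
    params = (params or SubjectParams()).resolved(protocol)
    hormones = hormones or HormoneParams()
    template = template or GroupTemplate(group)
    model = _Model(params, hormones, protocol, meal, insulin)

    t_start = protocol.runin_start
    if controller is not None:
        sim_end = max(sim_end,
                      protocol.hypo_window[1] + controller.restoration_duration)
    times: list[float] = []
    states: list[np.ndarray] = []
    girs: list[float] = []

    def record(t, y, gir):
        times.append(float(t))
        states.append(y.copy())
        girs.append(gir)

    def integrate(y, t0, t1, gir):
        # make the recorded GIR right-continuous: the rate stamped at a
        # switch node is the rate applying from that node onward
        if times and times[-1] == t0:
            girs[-1] = gir
        return _rk4(model, y, t0, t1, gir, fine_dt, record)

    y = model.initial_state()
    record(t_start, y, 0.0)
    y = integrate(y, t_start, protocol.insulin_start, 0.0)

    achieved = protocol.hypo_window
    if controller is not None and insulin:
        box = {"y": y}

        def step(gir, t0, t1):
            box["y"] = integrate(box["y"], t0, t1, gir)
            return float(box["y"][_G])

        _, _, _, achieved = run_closed_loop(step, float(y[_G]), controller,
                                            protocol)
        y = box["y"]
        t_now = times[-1]
    else:
        t_now = protocol.insulin_start
    if t_now < sim_end:
        y = integrate(y, t_now, sim_end, 0.0)

    truth = _build_truth(model, np.asarray(times), states, np.asarray(girs),
                         achieved)
    rec = _sample_record(truth, model, template, seed, subject_id, group,
                         noise)
    return rec, truth


def _build_truth(model: _Model, times, states, girs, achieved) -> TruthRecord:
    p = model.p
    n = len(times)
    arr = np.asarray(states)
    ra_o = np.empty(n); egp = np.empty(n); rd = np.empty(n); isr = np.empty(n)
    for i in range(n):
        ra_o[i], egp[i], rd[i], isr[i] = model.fluxes(times[i], arr[i])
    ra_tot = egp + ra_o + girs + model.proto.tracer_infusion
    g = arr[:, _G]
    c_tot = g * GLUCOSE_MMOL_L_TO_MG_ML
    tracee = c_tot - arr[:, _C1] - arr[:, _C2]
    z1 = arr[:, _C1] / tracee
    z2 = arr[:, _C2] / tracee
    depth = np.maximum(0.0, 3.5 - g)
    channels = {
        "glucose": g,
        "z1": z1,
        "z2": z2,
        "insulin": arr[:, _I_END],
        "c_peptide": arr[:, _QCP1] / p.cpeptide.v1,
        "aspart": arr[:, _I_ASP],
        "gir": girs,
        "heart_rate": p.hr_basal + p.hr_gain * depth,
        "bp_systolic": np.full(n, p.bp_sys),
        "bp_diastolic": p.bp_dia - p.bp_dia_drop * depth,
        "glp1": p.glp1_b + p.glp1_amp * ra_o,
    }
    for i, name in enumerate(HORMONES):
        channels[name] = arr[:, _H0 + i]
    return TruthRecord(times=times, ra_o=ra_o, egp=egp, rd=rd,
                       ra_tot=ra_tot, gir=np.asarray(girs, dtype=float),
                       isr=isr, channels=channels, params=p,
                       achieved_window=achieved)


def _sample_record(truth: TruthRecord, model: _Model,
                   template: GroupTemplate, seed, subject_id: str,
                   group: str, noise: bool) -> SubjectRecord:
    proto = model.proto
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    channels: dict[str, SampledSeries] = {}
    t_fine = truth.times
    for name in sorted(proto.sampling):
        grid = np.asarray(proto.sampling[name], dtype=float)
        grid = grid[(grid >= t_fine[0]) & (grid <= t_fine[-1])]
        if name.startswith("symptom_"):
            channels[name] = _symptom_series(name, grid, truth, template, rng)
            continue
        vals = np.interp(grid, t_fine, truth.channels[name])
        cv = template.cv_for(name) if noise else 0.0
        if cv > 0:
            vals = np.maximum(0.0, vals * (1.0 + cv * rng.standard_normal(len(vals))))
            if name == "glucose":
                vals = np.maximum(vals, 0.1)
        channels[name] = SampledSeries(grid, vals, name, CHANNEL_UNITS[name])
    # The simulated protocol always executes its nominal phases, so the
    # record carries the nominal window; truth.achieved_window keeps the
    # measured target-crossing diagnostic.  Right-shifted windows arise
    # only in measured data (where the sampling schedule shifts too).
    return SubjectRecord(
        subject_id=subject_id, group=group, body_weight=model.p.bw,
        age=model.p.age, sex=model.p.sex, height=model.p.height,
        channels=channels, hypo_window_actual=proto.hypo_window)


def _symptom_series(name: str, grid: np.ndarray, truth: TruthRecord,
                    template: GroupTemplate, rng) -> SampledSeries:
    item = name.removeprefix("symptom_")
    if item in SYMPTOM_ITEMS_AUTONOMIC:
        lam = 1.4
    elif item in SYMPTOM_ITEMS_NEUROGLYCOPENIC:
        lam = 0.6
    else:
        lam = 0.35
    lam *= template.symptom_intensity
    vals = np.minimum(7, 1 + rng.poisson(lam, size=len(grid)))
    return SampledSeries(grid, vals.astype(float), name, CHANNEL_UNITS[name])


# parameters given lognormal inter-subject spread (CV below); the
# distribution volumes vary less than kinetic parameters.
_VARIED_PARAMS = ("s_i", "egp_b", "k_empt", "k_abs", "beta_sec",
                  "cl_aspart", "cl_ins", "basal_isr")
_VARIED_CV = 0.15
_VG_CV = 0.05


def draw_subject_params(template: GroupTemplate, rng,
                        base: SubjectParams | None = None,
                        variability_cv: float = _VARIED_CV) -> SubjectParams:
    """Draw one subject's parameters from a group template.

    Template multipliers are applied to the base parameters, then each
    kinetic parameter gets an independent lognormal factor with the
    stated CV (mean 1); body weight, basal glucose, distribution volume
    and demographics get narrower spreads.
    """
    base = base or SubjectParams()
    kw: dict = {}
    for name in _VARIED_PARAMS:
        mult = template.param_multipliers.get(name, 1.0)
        kw[name] = getattr(base, name) * mult * _lognormal(rng, variability_cv)
    for name, mult in template.param_multipliers.items():
        if name not in kw:
            kw[name] = getattr(base, name) * mult
    kw["v_g"] = float(np.clip(base.v_g * _lognormal(rng, _VG_CV), 100.0, 300.0))
    kw["bw"] = base.bw * _lognormal(rng, 0.12)
    kw["g_b"] = float(np.clip(rng.normal(base.g_b, 0.15), 4.2, 5.6))
    kw["age"] = float(rng.uniform(30.0, 55.0))
    kw["sex"] = "M" if rng.random() < 1.0 / 8.0 else "F"
    kw["height"] = float(rng.normal(168.0, 6.0))
    return replace(base, **kw)


def _lognormal(rng, cv: float) -> float:
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return float(rng.lognormal(-0.5 * sigma * sigma, sigma))


def simulate_cohort(templates: dict[str, GroupTemplate] | None = None,
                    n_per_group: int = 8,
                    protocol: ProtocolConfig | None = None,
                    controller: ControllerConfig | None = None,
                    hormones: HormoneParams | None = None,
                    seed: int = 0,
                    noise: bool = True,
                    variability_cv: float = _VARIED_CV,
                    ) -> tuple[CohortDataset, list[TruthRecord]]:
    """Simulate a cohort of virtual subjects, one closed-loop clamp each.

    Per-subject seeds derive deterministically from the master seed, so
    identical seeds give identical cohorts.  Returns the sampled cohort
    and the parallel list of ground-truth records (same order as
    ``dataset.subjects``).
    """
    if n_per_group < 0:
        raise ValidationError("n_per_group must be >= 0")
    templates = templates or default_templates()
    protocol = protocol or ProtocolConfig()
    controller = controller if controller is not None else ControllerConfig()
    hormones = hormones or HormoneParams()
    master = np.random.SeedSequence(seed)
    subjects: list[SubjectRecord] = []
    truths: list[TruthRecord] = []
    for g_idx, (gname, template) in enumerate(sorted(templates.items())):
        for k in range(n_per_group):
            child = np.random.SeedSequence(entropy=master.entropy,
                                           spawn_key=(g_idx, k))
            rng = np.random.default_rng(child)
            params = draw_subject_params(template, rng,
                                         variability_cv=variability_cv)
            horm = hormones.scaled(template.hormone_multipliers)
            rec, truth = simulate_subject(
                params=params, hormones=horm, protocol=protocol,
                controller=controller,
                seed=np.random.SeedSequence(entropy=master.entropy,
                                            spawn_key=(g_idx, k, 1)),
                template=template,
                subject_id=f"{gname}{k + 1:02d}", group=gname,
                noise=noise)
            subjects.append(rec)
            truths.append(truth)
    dataset = CohortDataset(
        subjects=subjects, protocol=protocol,
        provenance={"source": "simulated", "seed": int(seed),
                    "generator": f"hypoclamp {_pkg_version}"})
    return dataset, truths
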