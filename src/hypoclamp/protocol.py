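"""Clamp protocol configuration.

The experimental protocol: a primed (3 mg/kg) continuous (30 ug/kg/min,
i.e. 0.03 mg/kg/min) infusion of an intravenous glucose tracer starting
100 min before the subject drinks 15 g of glucose labelled with a 1.5%
mass fraction of an oral tracer (t0, ingested over 5 min).  A fixed-rate
insulin infusion (0.0623 U/kg/h) starts at t90; a controller modulates
an exogenous glucose infusion (GIR) so that blood glucose reaches the
hypoglycaemic target of 2.5 mmol/l at t150, holds it for 20 min, and
restores euglycaemia after t170.

All times are minutes relative to the oral glucose load (t0); the run-in
period therefore has negative times.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import yaml

from .exceptions import ProtocolError

#: Canonical units per recorded channel.  Symptom items share one entry
#: via the ``symptom_`` prefix.
CHANNEL_UNITS: dict[str, str] = {
    "glucose": "mmol/l",
    "z1": "",            # iv tracer-to-tracee ratio, dimensionless
    "z2": "",            # oral tracer-to-tracee ratio, dimensionless
    "insulin": "pmol/l",         # endogenous insulin
    "c_peptide": "pmol/l",
    "aspart": "pmol/l",          # exogenous insulin analogue
    "glucagon": "pmol/l",
    "pp": "pmol/l",
    "glp1": "pmol/l",
    "adrenaline": "nmol/l",
    "noradrenaline": "nmol/l",
    "cortisol": "nmol/l",
    "gh": "ug/l",
    "gir": "mg/kg/min",
    "heart_rate": "bpm",
    "bp_systolic": "mmHg",
    "bp_diastolic": "mmHg",
}

#: The 11 hypoglycaemia symptom items, grouped by subscale.
SYMPTOM_ITEMS_AUTONOMIC = ("sweating", "palpitations", "tremor", "hunger")
SYMPTOM_ITEMS_NEUROGLYCOPENIC = (
    "confusion", "dizziness", "odd_behaviour", "speech_difficulty",
    "incoordination",
)
SYMPTOM_ITEMS_MALAISE = ("headache", "nausea")
SYMPTOM_ITEMS = (
    SYMPTOM_ITEMS_AUTONOMIC
    + SYMPTOM_ITEMS_NEUROGLYCOPENIC
    + SYMPTOM_ITEMS_MALAISE
)

for _item in SYMPTOM_ITEMS:
    CHANNEL_UNITS[f"symptom_{_item}"] = "score"


def channel_units(channel: str) -> str | None:
    """Canonical units for a channel name, or None if unknown."""
    return CHANNEL_UNITS.get(channel)


def _default_sampling() -> dict[str, tuple[float, ...]]:
    # Blood glucose: background, pre-meal, then every 15 min to t75 and
    # every 5 min thereafter (meter cadence of the protocol).
    glucose = [-100.0, -30.0] + list(range(0, 76, 15)) + list(range(80, 201, 5))
    # Enrichments: background sample, basal samples once the tracer has
    # neared plateau (anchoring the fasting turnover estimate), then a
    # 10-min grid spanning the meal and the clamp.
    enrich = [-100.0, -40.0, -30.0] + list(range(-20, 181, 10))
    hormones = [0.0, 15.0, 30.0, 45.0, 60.0, 85.0, 120.0,
                150.0, 155.0, 160.0, 165.0, 170.0]
    grids: dict[str, tuple[float, ...]] = {
        "glucose": tuple(float(t) for t in glucose),
        "z1": tuple(float(t) for t in enrich),
        "z2": tuple(float(t) for t in enrich),
        "gir": tuple(float(t) for t in range(0, 201, 5)),
        "heart_rate": tuple(float(t) for t in range(0, 201, 5)),
        "pp": (0.0, 85.0, 160.0),
        "glp1": (0.0, 85.0, 160.0),
        "bp_systolic": (0.0, 165.0),
        "bp_diastolic": (0.0, 165.0),
    }
    for ch in ("insulin", "c_peptide", "aspart", "glucagon", "adrenaline",
               "noradrenaline", "cortisol", "gh"):
        grids[ch] = tuple(hormones)
    for item in SYMPTOM_ITEMS:
        grids[f"symptom_{item}"] = (165.0,)
    return grids


@dataclass(frozen=True)
class ProtocolConfig:
    """Timing and dose constants of the clamp experiment.

    Parameters
    ----------
    prime_dose : float
        Intravenous tracer priming bolus, mg per kg body weight.
    tracer_infusion : float
        Continuous iv tracer infusion rate F, mg/kg/min.
    runin_start : float
        Start of the tracer run-in, min (negative: before the meal).
    oral_dose : float
        Oral glucose load D, mg (15 g).
    oral_label_fraction : float
        Tracer mass fraction of the drink (dimensionless).
    ingestion_duration : float
        Duration over which the drink is consumed, min.
    insulin_start : float
        Start of the insulin infusion, min.
    insulin_rate : float
        Insulin infusion rate, U/kg/h.
    hypo_target : float
        Clamp target during the hypoglycaemic window, mmol/l.
    hypo_window : tuple
        Nominal hypoglycaemic window [start, end], min.
    postprandial_window : tuple
        Window over which postprandial metrics are computed, min.
    sampling : dict
        Per-channel sampling times (min, strictly increasing).
    """

    prime_dose: float = 3.0
    tracer_infusion: float = 0.03
    runin_start: float = -100.0
    oral_dose: float = 15000.0
    oral_label_fraction: float = 0.015
    ingestion_duration: float = 5.0
    insulin_start: float = 90.0
    insulin_rate: float = 0.0623
    hypo_target: float = 2.5
    hypo_window: tuple[float, float] = (150.0, 170.0)
    postprandial_window: tuple[float, float] = (0.0, 85.0)
    sampling: dict[str, tuple[float, ...]] = field(default_factory=_default_sampling)

    def __post_init__(self) -> None:
        for name in ("prime_dose", "tracer_infusion", "oral_dose",
                     "ingestion_duration", "insulin_rate"):
            if getattr(self, name) <= 0:
                raise ProtocolError(f"{name} must be positive")
        if not (0.0 < self.oral_label_fraction < 0.5):
            raise ProtocolError("oral_label_fraction must lie in (0, 0.5)")
        if not (self.hypo_window[0] > self.insulin_start > 0):
            raise ProtocolError(
                "need hypo_window start > insulin_start > 0, got "
                f"{self.hypo_window[0]} and {self.insulin_start}")
        if self.hypo_window[1] <= self.hypo_window[0]:
            raise ProtocolError("hypo_window must have positive duration")
        if self.hypo_target <= 0:
            raise ProtocolError("hypo_target must be positive")
        for channel, times in self.sampling.items():
            t = tuple(times)
            if any(b <= a for a, b in zip(t, t[1:])):
                raise ProtocolError(
                    f"sampling times for {channel!r} must be strictly increasing")

    @property
    def insulin_rate_pmol_kg_min(self) -> float:
        """Insulin infusion rate in pmol/kg/min (1 U = 6 nmol)."""
        return self.insulin_rate * 100.0

    @property
    def hypo_duration(self) -> float:
        return self.hypo_window[1] - self.hypo_window[0]

    def with_updates(self, **kwargs) -> "ProtocolConfig":
        """Copy with selected fields replaced."""
        return replace(self, **kwargs)

    # -- serialisation ----------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["hypo_window"] = list(self.hypo_window)
        d["postprandial_window"] = list(self.postprandial_window)
        d["sampling"] = {k: list(v) for k, v in self.sampling.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ProtocolConfig":
        d = dict(d)
        if "hypo_window" in d:
            d["hypo_window"] = tuple(d["hypo_window"])
        if "postprandial_window" in d:
            d["postprandial_window"] = tuple(d["postprandial_window"])
        if "sampling" in d:
            d["sampling"] = {k: tuple(v) for k, v in d["sampling"].items()}
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ProtocolConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
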