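"""In-memory data model: sampled series, subjects and cohorts."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import ValidationError
from .protocol import CHANNEL_UNITS, ProtocolConfig

GROUPS = ("PBH", "RYGB", "SG", "CN")


@dataclass
class SampledSeries:
    """One measured channel: values on a strictly increasing time grid.

    Times are minutes relative to the oral glucose load; units are the
    channel's canonical units (see :data:`hypoclamp.protocol.CHANNEL_UNITS`).
    """

    times: np.ndarray
    values: np.ndarray
    channel: str
    units: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.values.ndim != 1:
            raise ValidationError(f"{self.channel}: times/values must be 1-D")
        if len(self.times) != len(self.values):
            raise ValidationError(
                f"{self.channel}: {len(self.times)} times vs "
                f"{len(self.values)} values")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValidationError(
                f"{self.channel}: times must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError(f"{self.channel}: non-finite values")

    def __len__(self) -> int:
        return len(self.times)

    def value_at(self, t: float, tol: float = 1e-9) -> float:
        """Value at an exact sample time (within ``tol``)."""
        idx = np.nonzero(np.abs(self.times - t) <= tol)[0]
        if len(idx) == 0:
            raise ValidationError(
                f"{self.channel}: no sample at t={t} min")
        return float(self.values[idx[0]])

    def interp(self, t) -> np.ndarray:
        """Linear interpolation inside the sampled span."""
        t = np.asarray(t, dtype=float)
        if np.any(t < self.times[0]) or np.any(t > self.times[-1]):
            raise ValidationError(
                f"{self.channel}: interpolation outside sampled span")
        return np.interp(t, self.times, self.values)

    def window(self, window: tuple[float, float]) -> "SampledSeries":
        """Sub-series of samples with window[0] <= t <= window[1]."""
        lo, hi = window
        mask = (self.times >= lo) & (self.times <= hi)
        return SampledSeries(self.times[mask], self.values[mask],
                             self.channel, self.units)

    def equals(self, other: "SampledSeries", tol: float = 1e-9) -> bool:
        return (self.channel == other.channel
                and self.units == other.units
                and len(self) == len(other)
                and np.allclose(self.times, other.times, atol=tol, rtol=0)
                and np.allclose(self.values, other.values, atol=tol, rtol=0))


@dataclass
class SubjectRecord:
    """One subject's multichannel clamp record.

    ``hypo_window_actual`` is the achieved 20-min hypoglycaemic window,
    which may sit later than the nominal [150, 170] when the plateau was
    reached late; ``alignment_shift`` records any rigid shift applied by
    :func:`hypoclamp.io.align_hypo_window`.
    """

    subject_id: str
    group: str
    body_weight: float
    age: float = 45.0
    sex: str = "F"
    height: float = 168.0
    channels: dict[str, SampledSeries] = field(default_factory=dict)
    hypo_window_actual: tuple[float, float] = (150.0, 170.0)
    alignment_shift: float = 0.0

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(
                f"unknown group {self.group!r}; expected one of {GROUPS}")
        if self.body_weight <= 0:
            raise ValidationError("body_weight must be positive")
        for name, series in self.channels.items():
            if name not in CHANNEL_UNITS:
                raise ValidationError(f"unknown channel {name!r}")
            if name == "glucose" and np.any(series.values <= 0):
                raise ValidationError("glucose values must be positive")
            if name in ("z1", "z2") and np.any(series.values < 0):
                raise ValidationError(f"{name}: tracer ratios must be >= 0")
            if name.startswith("symptom_"):
                v = series.values
                if not np.allclose(v, np.round(v)) or np.any(v < 1) or np.any(v > 7):
                    raise ValidationError(
                        f"{name}: ratings must be integers in [1, 7]")

    def channel(self, name: str) -> SampledSeries:
        if name not in self.channels:
            raise ValidationError(
                f"subject {self.subject_id}: channel {name!r} not recorded")
        return self.channels[name]

    def has_channel(self, name: str) -> bool:
        return name in self.channels

    def replace(self, **kwargs) -> "SubjectRecord":
        return replace(self, **kwargs)


@dataclass
class CohortDataset:
    """A set of subject records sharing one protocol."""

    subjects: list[SubjectRecord]
    protocol: ProtocolConfig
    provenance: dict = field(default_factory=lambda: {"source": "measured"})

    def __post_init__(self) -> None:
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise ValidationError("subject_ids must be unique")

    def __len__(self) -> int:
        return len(self.subjects)

    def by_group(self) -> dict[str, list[SubjectRecord]]:
        out: dict[str, list[SubjectRecord]] = {}
        for s in self.subjects:
            out.setdefault(s.group, []).append(s)
        return out

    def group_sizes(self) -> dict[str, int]:
        return {g: len(v) for g, v in self.by_group().items()}

    def subject(self, subject_id: str) -> SubjectRecord:
        for s in self.subjects:
            if s.subject_id == subject_id:
                return s
        raise ValidationError(f"no subject {subject_id!r} in cohort")
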