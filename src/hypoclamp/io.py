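"""Cohort file I/O and hypoglycaemic-window alignment.

The canonical interchange is long-format CSV (one row per observation),
because the channels are sampled on heterogeneous grids.  A cohort on
disk is a directory holding

* ``observations.csv`` — subject_id, group, time_min, channel, value, units
* ``subjects.csv``     — per-subject metadata incl. the achieved window
* ``protocol.yaml``    — the protocol constants

Values carried in non-canonical but convertible units (e.g. glucose in
mg/dl) are converted on read; unknown channels or unconvertible units are
rejected.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .exceptions import AlignmentError, ValidationError
from .protocol import CHANNEL_UNITS, ProtocolConfig
from .records import CohortDataset, SampledSeries, SubjectRecord
from .units import can_convert, convert_units

_OBS_COLUMNS = ["subject_id", "group", "time_min", "channel", "value", "units"]
_SUBJ_COLUMNS = ["subject_id", "group", "body_weight", "age", "sex", "height",
                 "hypo_start", "hypo_end", "alignment_shift"]


def write_cohort(dataset: CohortDataset, path: str) -> None:
    """Write a cohort as long-format CSV files under directory ``path``."""
    os.makedirs(path, exist_ok=True)
    obs_rows = []
    subj_rows = []
    for s in dataset.subjects:
        subj_rows.append({
            "subject_id": s.subject_id, "group": s.group,
            "body_weight": s.body_weight, "age": s.age, "sex": s.sex,
            "height": s.height, "hypo_start": s.hypo_window_actual[0],
            "hypo_end": s.hypo_window_actual[1],
            "alignment_shift": s.alignment_shift,
        })
        for name, series in sorted(s.channels.items()):
            for t, v in zip(series.times, series.values):
                obs_rows.append({
                    "subject_id": s.subject_id, "group": s.group,
                    "time_min": t, "channel": name, "value": v,
                    "units": series.units,
                })
    pd.DataFrame(obs_rows, columns=_OBS_COLUMNS).to_csv(
        os.path.join(path, "observations.csv"), index=False,
        float_format="%.17g")
    pd.DataFrame(subj_rows, columns=_SUBJ_COLUMNS).to_csv(
        os.path.join(path, "subjects.csv"), index=False, float_format="%.17g")
    dataset.protocol.to_yaml(os.path.join(path, "protocol.yaml"))


def read_cohort(path: str, protocol: ProtocolConfig | None = None) -> CohortDataset:
    """Read a cohort directory written by :func:`write_cohort`.

    Parameters
    ----------
    path : str
        Cohort directory.
    protocol : ProtocolConfig, optional
        Overrides the protocol stored alongside the data.

    Raises
    ------
    ValidationError
        On unknown channels, unconvertible units, duplicated time points
        or non-monotone time stamps.
    """
    obs = pd.read_csv(os.path.join(path, "observations.csv"))
    missing = set(_OBS_COLUMNS) - set(obs.columns)
    if missing:
        raise ValidationError(f"observations.csv lacks columns {sorted(missing)}")
    subj = pd.read_csv(os.path.join(path, "subjects.csv"))
    if protocol is None:
        proto_path = os.path.join(path, "protocol.yaml")
        protocol = (ProtocolConfig.from_yaml(proto_path)
                    if os.path.exists(proto_path) else ProtocolConfig())

    obs["units"] = obs["units"].fillna("")
    subjects = []
    for _, row in subj.iterrows():
        sid = str(row["subject_id"])
        sub_obs = obs[obs["subject_id"].astype(str) == sid]
        channels: dict[str, SampledSeries] = {}
        for name, grp in sub_obs.groupby("channel"):
            name = str(name)
            canonical = CHANNEL_UNITS.get(name)
            if canonical is None:
                raise ValidationError(f"unknown channel {name!r} for {sid}")
            grp = grp.sort_values("time_min")
            times = grp["time_min"].to_numpy(dtype=float)
            if len(times) > 1 and np.any(np.diff(times) <= 0):
                raise ValidationError(
                    f"{sid}/{name}: duplicated or non-monotone time points")
            values = grp["value"].to_numpy(dtype=float)
            declared = set(grp["units"].astype(str))
            if len(declared) > 1:
                raise ValidationError(f"{sid}/{name}: inconsistent units {declared}")
            units = declared.pop()
            if units != canonical:
                if not can_convert(units, canonical):
                    raise ValidationError(
                        f"{sid}/{name}: cannot convert {units!r} to {canonical!r}")
                values = convert_units(values, units, canonical)
            channels[name] = SampledSeries(times, values, name, canonical)
        subjects.append(SubjectRecord(
            subject_id=sid, group=str(row["group"]),
            body_weight=float(row["body_weight"]), age=float(row["age"]),
            sex=str(row["sex"]), height=float(row["height"]),
            channels=channels,
            hypo_window_actual=(float(row["hypo_start"]), float(row["hypo_end"])),
            alignment_shift=float(row.get("alignment_shift", 0.0)),
        ))
    return CohortDataset(subjects=subjects, protocol=protocol,
                         provenance={"source": str(path)})


def require_channels(record: SubjectRecord, names: list[str], analysis: str) -> None:
    """Raise a named error if a record lacks channels an analysis needs."""
    absent = [n for n in names if not record.has_channel(n)]
    if absent:
        raise ValidationError(
            f"subject {record.subject_id}: analysis {analysis!r} requires "
            f"missing channel(s) {absent}")


def align_hypo_window(record: SubjectRecord,
                      protocol: ProtocolConfig) -> SubjectRecord:
    """Map a right-shifted achieved hypoglycaemic window onto the nominal one.

    When the plateau was reached late, the whole insulin-phase timeline is
    rigidly shifted by ``nominal_start - actual_start`` so the achieved
    window lands on the nominal [150, 170]; samples before the insulin
    start are untouched (the postprandial window is never distorted).
    The applied shift is recorded on the returned record.

    Raises
    ------
    AlignmentError
        If the achieved window does not have the nominal 20-min duration,
        or if shifting would break time ordering within a channel.
    """
    lo, hi = record.hypo_window_actual
    nominal = protocol.hypo_window
    if abs((hi - lo) - protocol.hypo_duration) > 1e-9:
        raise AlignmentError(
            f"subject {record.subject_id}: achieved window [{lo}, {hi}] does "
            f"not have the nominal {protocol.hypo_duration:g}-min duration")
    shift = nominal[0] - lo
    if shift == 0.0:
        return record
    t_ins = protocol.insulin_start
    channels = {}
    for name, series in record.channels.items():
        times = series.times.copy()
        post = times >= t_ins
        times[post] = times[post] + shift
        if len(times) > 1 and np.any(np.diff(times) <= 0):
            raise AlignmentError(
                f"subject {record.subject_id}/{name}: shifting by {shift:g} min "
                "would break time ordering")
        channels[name] = SampledSeries(times, series.values.copy(),
                                       name, series.units)
    return record.replace(channels=channels, hypo_window_actual=nominal,
                          alignment_shift=shift)


def align_cohort(dataset: CohortDataset) -> CohortDataset:
    """Align every subject's hypoglycaemic window (see align_hypo_window)."""
    aligned = [align_hypo_window(s, dataset.protocol) for s in dataset.subjects]
    return CohortDataset(subjects=aligned, protocol=dataset.protocol,
                         provenance=dict(dataset.provenance, aligned=True))
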