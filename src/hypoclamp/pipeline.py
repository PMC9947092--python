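"""End-to-end cohort analysis: per-subject outcome metrics and group
comparison tables.

This glues the stages together the way the full study analysis runs:
align the hypoglycaemic windows, estimate glucose fluxes per subject,
deconvolve the insulin secretion rate, and reduce everything to the
outcome metrics that are then compared across groups.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .fluxes import SteeleConfig, estimate_fluxes, postprandial_flux_metrics
from .io import align_cohort
from .protocol import SYMPTOM_ITEMS, ProtocolConfig
from .records import CohortDataset, SubjectRecord
from .secretion import (DeconvConfig, insulin_sensitivity_window,
                        isr_deconvolve, total_insulin_clearance,
                        posthepatic_clearance, homa_classic)
from .stats import (GroupComparison, SymptomRating, auc_trapezoid,
                    compare_groups, iauc, peak_metrics, symptom_scores,
                    window_stats)

#: variables compared across groups by default
DEFAULT_COMPARISONS = (
    "glucagon_iauc_hypo", "adrenaline_iauc_hypo", "noradrenaline_iauc_hypo",
    "cortisol_iauc_hypo", "gh_iauc_hypo", "pp_t160", "glp1_t160",
    "glucose_mean_hypo", "glucose_cv_hypo", "gir_grams_hypo",
    "egp_auc_hypo", "recovery_percent", "egp_suppression_t15",
    "auc0_15_rao", "peak_glucose", "peak_insulin", "isr_auc_pp",
    "si_postprandial", "si_hypo", "total_insulin_clearance_pp",
    "posthepatic_clearance_hypo", "symptom_total",
)


def subject_metrics(record: SubjectRecord, protocol: ProtocolConfig,
                    steele: SteeleConfig | None = None,
                    deconv: DeconvConfig | None = None) -> dict[str, float]:
    """All per-subject outcome metrics as a flat dict.

    Metrics whose inputs are missing from the record are simply absent
    from the result (e.g. no symptom channels -> no symptom scores).
    """
    steele = steele or SteeleConfig()
    deconv = deconv or DeconvConfig()
    hypo = protocol.hypo_window
    pp = protocol.postprandial_window
    t85 = pp[1]
    out: dict[str, float] = {}

    glucose = record.channel("glucose")
    m, _, cv = window_stats(glucose, hypo)
    out["glucose_mean_hypo"] = m
    out["glucose_cv_hypo"] = cv
    out["peak_glucose"], out["time_to_peak_glucose"] = peak_metrics(glucose, pp)
    out["fasting_glucose"] = glucose.value_at(0.0)

    if record.has_channel("insulin"):
        insulin = record.channel("insulin")
        out["peak_insulin"], out["time_to_peak_insulin"] = \
            peak_metrics(insulin, pp)
        out["fasting_insulin"] = insulin.value_at(0.0)
        out["homa_ir"] = homa_classic(out["fasting_glucose"],
                                      out["fasting_insulin"])
        out["insulin_mean_hypo"] = window_stats(insulin, hypo)[0]

    for hormone in ("glucagon", "adrenaline", "noradrenaline",
                    "cortisol", "gh"):
        if record.has_channel(hormone):
            s = record.channel(hormone)
            out[f"{hormone}_iauc_hypo"] = iauc(s, hypo, t85)
            out[f"{hormone}_mean_hypo"] = window_stats(s, hypo)[0]
    for hormone in ("pp", "glp1"):
        if record.has_channel(hormone):
            out[f"{hormone}_t160"] = record.channel(hormone).value_at(160.0)

    if record.has_channel("gir"):
        gir = record.channel("gir")
        # grams infused over the window: AUC [mg/kg/min * min] * kg / 1000
        out["gir_grams_hypo"] = (auc_trapezoid(gir, hypo)
                                 * record.body_weight / 1000.0)

    if record.has_channel("heart_rate"):
        out["heart_rate_mean_hypo"] = \
            window_stats(record.channel("heart_rate"), hypo)[0]
    for ch in ("bp_systolic", "bp_diastolic"):
        if record.has_channel(ch):
            s = record.channel(ch)
            out[f"{ch}_delta"] = s.value_at(165.0) - s.value_at(0.0)

    if all(record.has_channel(c) for c in ("z1", "z2")):
        profile = estimate_fluxes(record, protocol, steele)
        out.update(postprandial_flux_metrics(profile, protocol,
                                             record.body_weight))
        out["egp_auc_hypo"] = auc_trapezoid(profile.series("egp"), hypo)
        out["egp_mean_hypo"] = out["egp_auc_hypo"] / protocol.hypo_duration
        out["clipped_fraction"] = profile.diagnostics["clipped_fraction"]
        rd_series = profile.series("rd")
        if record.has_channel("insulin"):
            out["si_postprandial"] = insulin_sensitivity_window(
                rd_series, glucose, [record.channel("insulin")], pp)
            if record.has_channel("aspart"):
                out["si_hypo"] = insulin_sensitivity_window(
                    rd_series, glucose,
                    [record.channel("insulin"), record.channel("aspart")],
                    hypo)

    if record.has_channel("c_peptide") and record.has_channel("insulin"):
        from .secretion import CPeptideKinetics
        kin = CPeptideKinetics.population(
            age=record.age, sex=record.sex, height_cm=record.height,
            weight_kg=record.body_weight)
        isr = isr_deconvolve(record.channel("c_peptide"), kin, deconv,
                             bw=record.body_weight)
        isr_series = isr.series()
        if isr_series.times[0] <= pp[0] and isr_series.times[-1] >= pp[1]:
            out["isr_auc_pp"] = auc_trapezoid(isr_series, pp)
            out["peak_isr"], _ = peak_metrics(isr_series, pp)
            out["total_insulin_clearance_pp"] = total_insulin_clearance(
                isr_series, record.channel("insulin"), pp)

    if record.has_channel("aspart"):
        rate = protocol.insulin_rate_pmol_kg_min
        t_ins, t_stop = protocol.insulin_start, protocol.hypo_window[1]

        def infusion(t):
            t = np.asarray(t, dtype=float)
            return np.where((t >= t_ins) & (t < t_stop), rate, 0.0)

        try:
            out["posthepatic_clearance_hypo"] = posthepatic_clearance(
                record.channel("aspart"), infusion, hypo)
        except Exception:
            pass   # too few analogue samples in the window

    if all(record.has_channel(f"symptom_{i}") for i in SYMPTOM_ITEMS):
        rating = SymptomRating({
            i: int(record.channel(f"symptom_{i}").value_at(165.0))
            for i in SYMPTOM_ITEMS})
        for k, v in symptom_scores(rating).items():
            out[f"symptom_{k}"] = v
    return out


def analyze_cohort(dataset: CohortDataset,
                   steele: SteeleConfig | None = None,
                   deconv: DeconvConfig | None = None,
                   align: bool = True) -> pd.DataFrame:
    """Per-subject metrics table (one row per subject)."""
    if align:
        dataset = align_cohort(dataset)
    rows = []
    for rec in dataset.subjects:
        row = {"subject_id": rec.subject_id, "group": rec.group,
               "body_weight": rec.body_weight}
        row.update(subject_metrics(rec, dataset.protocol, steele, deconv))
        rows.append(row)
    return pd.DataFrame(rows)


def compare_cohort(metrics: pd.DataFrame,
                   variables: tuple[str, ...] = DEFAULT_COMPARISONS,
                   alpha: float = 0.05) -> list[GroupComparison]:
    """Run the statistical cascade on each metric present in the table."""
    results = []
    for var in variables:
        if var not in metrics.columns:
            continue
        sub = metrics[["group", var]].dropna()
        by_group = {g: d[var].to_numpy() for g, d in sub.groupby("group")}
        if len(by_group) < 2 or any(len(v) < 3 for v in by_group.values()):
            continue
        results.append(compare_groups(by_group, alpha=alpha, variable=var))
    return results


def comparison_table(results: list[GroupComparison]) -> pd.DataFrame:
    """Results as a flat table: one row per variable per group, plus the
    global test columns (the layout of a clinical characteristics table)."""
    rows = []
    for r in results:
        for group, (med, q1, q3) in r.summaries.items():
            rows.append({
                "variable": r.variable, "group": group, "median": med,
                "q1": q1, "q3": q3, "test": r.test_used,
                "p_global": r.p_global, "posthoc": r.posthoc_method,
            })
    return pd.DataFrame(rows)
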