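"""Outcome metrics and group-comparison statistics.

Window summaries (trapezoidal AUC and incremental AUC, means, CV, peaks,
symptom sum scores) and the study's statistical cascade: one-way ANOVA
on raw values when its assumptions hold, ANOVA after log transformation
otherwise, and Kruskal-Wallis when the assumptions still fail; post hoc
comparisons by Tukey's HSD on the ANOVA paths and pairwise Mann-Whitney
on the Kruskal-Wallis path.  The assumption checks are Shapiro-Wilk on
the residuals and Levene's test for homogeneity, both at 0.05 — the
most common operationalisation of "the ANOVA assumptions".
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .exceptions import EstimationError, ValidationError
from .protocol import (SYMPTOM_ITEMS, SYMPTOM_ITEMS_AUTONOMIC,
                       SYMPTOM_ITEMS_MALAISE, SYMPTOM_ITEMS_NEUROGLYCOPENIC)
from .records import SampledSeries


# ---------------------------------------------------------------------------
# window summaries
# ---------------------------------------------------------------------------

def _window_points(series: SampledSeries,
                   window: tuple[float, float]) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = window
    if lo < series.times[0] - 1e-9 or hi > series.times[-1] + 1e-9:
        raise EstimationError(
            f"{series.channel}: window [{lo:g}, {hi:g}] outside sampled span "
            f"[{series.times[0]:g}, {series.times[-1]:g}]")
    mask = (series.times >= lo - 1e-9) & (series.times <= hi + 1e-9)
    t = series.times[mask]
    v = series.values[mask]
    if len(t) == 0 or t[0] > lo + 1e-9:
        t = np.insert(t, 0, lo)
        v = np.insert(v, 0, series.interp(lo))
    if t[-1] < hi - 1e-9:
        t = np.append(t, hi)
        v = np.append(v, series.interp(hi))
    return t, v


def auc_trapezoid(series: SampledSeries, window: tuple[float, float]) -> float:
    """Trapezoidal area under the curve over a window (value * min).

    Window endpoints falling between samples are linearly interpolated;
    a window outside the sampled span is an error.
    """
    t, v = _window_points(series, window)
    return float(np.trapezoid(v, t))


def iauc(series: SampledSeries, window: tuple[float, float],
         baseline_time: float) -> float:
    """Incremental AUC: trapezoidal area of (value - value(baseline))
    over the window.  The baseline must be an actual sample; excursions
    below baseline contribute negatively (no truncation)."""
    baseline = series.value_at(baseline_time)
    t, v = _window_points(series, window)
    return float(np.trapezoid(v - baseline, t))


def window_stats(series: SampledSeries,
                 window: tuple[float, float]) -> tuple[float, float, float]:
    """(mean, SD, CV) of the samples inside a window.

    Plain sample statistics of the observations (the clamp-quality CV is
    the SD divided by the mean of the measured values, not a
    time-weighted quantity).  Empty windows are an error.
    """
    sub = series.window(window)
    if len(sub) == 0:
        raise EstimationError(
            f"{series.channel}: no samples in window {window}")
    mean = float(np.mean(sub.values))
    sd = float(np.std(sub.values, ddof=1)) if len(sub) > 1 else 0.0
    cv = sd / mean if mean != 0 else math.inf
    return mean, sd, cv


def peak_metrics(series: SampledSeries,
                 window: tuple[float, float]) -> tuple[float, float]:
    """(peak value, time to peak) within a window; ties broken by the
    earliest time."""
    sub = series.window(window)
    if len(sub) == 0:
        raise EstimationError(
            f"{series.channel}: no samples in window {window}")
    i = int(np.argmax(sub.values))
    return float(sub.values[i]), float(sub.times[i])


# ---------------------------------------------------------------------------
# symptom scores
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SymptomRating:
    """One administration of the 11-item hypoglycaemia symptom scale.

    Four autonomic items (sweating, palpitations, tremor, hunger), five
    neuroglycopenic items (confusion, dizziness, odd behaviour, speech
    difficulties, incoordination) and two general-malaise items
    (headache, nausea), each rated 1 (absent) to 7 (severe).
    """

    items: dict[str, int]

    def __post_init__(self) -> None:
        if set(self.items) != set(SYMPTOM_ITEMS):
            raise ValidationError(
                f"expected exactly the items {sorted(SYMPTOM_ITEMS)}")
        for name, v in self.items.items():
            if not (isinstance(v, (int, np.integer)) and 1 <= v <= 7):
                raise ValidationError(
                    f"rating {name}={v!r} must be an integer in [1, 7]")

    @classmethod
    def uniform(cls, value: int) -> "SymptomRating":
        return cls({item: value for item in SYMPTOM_ITEMS})


def symptom_scores(rating: SymptomRating) -> dict[str, int]:
    """Sum scores: total (range 11-77), autonomic (4-28),
    neuroglycopenic (5-35) and general malaise (2-14)."""
    auto = sum(rating.items[i] for i in SYMPTOM_ITEMS_AUTONOMIC)
    neuro = sum(rating.items[i] for i in SYMPTOM_ITEMS_NEUROGLYCOPENIC)
    malaise = sum(rating.items[i] for i in SYMPTOM_ITEMS_MALAISE)
    return {"total": auto + neuro + malaise, "autonomic": auto,
            "neuroglycopenic": neuro, "malaise": malaise}


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------

@dataclass
class GroupComparison:
    """Result of the ANOVA / log-ANOVA / Kruskal-Wallis cascade."""

    variable: str
    summaries: dict[str, tuple[float, float, float]]   # group -> (median, q1, q3)
    test_used: str                    # anova | anova_log | kruskal | degenerate
    p_global: float
    posthoc_method: str               # tukey | mannwhitney | none
    pairwise: dict[tuple[str, str], float]
    trail: list[tuple[str, float]] = field(default_factory=list)


def _anova_assumptions_ok(groups: list[np.ndarray], alpha: float,
                          trail: list, label: str) -> bool:
    resid = np.concatenate([g - g.mean() for g in groups])
    if np.allclose(resid, 0.0):
        trail.append((f"{label}:constant_residuals", 1.0))
        return True
    p_sw = float(sps.shapiro(resid).pvalue)
    trail.append((f"{label}:shapiro_residuals", p_sw))
    p_lev = float(sps.levene(*groups).pvalue)
    trail.append((f"{label}:levene", p_lev))
    return p_sw >= alpha and p_lev >= alpha


def compare_groups(values_by_group: dict[str, np.ndarray],
                   alpha: float = 0.05,
                   variable: str = "",
                   posthoc: bool = True,
                   force: str | None = None) -> GroupComparison:
    """Compare a variable across groups with the assumption cascade.

    Raw one-way ANOVA if Shapiro-Wilk (residuals) and Levene both pass
    at 0.05; otherwise ANOVA on log-transformed values (only if all
    values are positive); otherwise Kruskal-Wallis.  Post hoc: Tukey HSD
    on the ANOVA paths, pairwise two-sided Mann-Whitney on the
    Kruskal-Wallis path.  The executed checks are recorded in ``trail``.
    ``posthoc=False`` skips the pairwise tests (global p only);
    ``force`` overrides the cascade ("anova" or "kruskal").
    """
    names = list(values_by_group)
    groups = [np.asarray(values_by_group[g], dtype=float) for g in names]
    if len(groups) < 2:
        raise EstimationError("need at least 2 groups")
    if any(len(g) < 3 for g in groups):
        raise EstimationError("need at least 3 values per group")
    summaries = {
        n: (float(np.median(g)), float(np.percentile(g, 25)),
            float(np.percentile(g, 75)))
        for n, g in zip(names, groups)}
    trail: list[tuple[str, float]] = []

    allv = np.concatenate(groups)
    if np.allclose(allv, allv[0]):
        return GroupComparison(variable, summaries, "degenerate", 1.0,
                               "none", {}, [("all_values_equal", 1.0)])

    def _tukey(gs, tag):
        data = np.concatenate(gs)
        labels = np.concatenate([[n] * len(g) for n, g in zip(names, gs)])
        res = pairwise_tukeyhsd(data, labels, alpha=alpha)
        pairs = {}
        for (a, b), p in zip(itertools.combinations(sorted(names), 2),
                             res.pvalues):
            pairs[(a, b)] = float(p)
        return pairs

    if force not in (None, "anova", "kruskal"):
        raise EstimationError(f"unknown forced path {force!r}")
    if force == "anova" or (force is None
                            and _anova_assumptions_ok(groups, alpha, trail,
                                                      "raw")):
        p = float(sps.f_oneway(*groups).pvalue)
        return GroupComparison(variable, summaries, "anova", p, "tukey",
                               _tukey(groups, "raw") if posthoc else {}, trail)
    if force is None and all(np.all(g > 0) for g in groups):
        logs = [np.log(g) for g in groups]
        if _anova_assumptions_ok(logs, alpha, trail, "log"):
            p = float(sps.f_oneway(*logs).pvalue)
            return GroupComparison(variable, summaries, "anova_log", p,
                                   "tukey",
                                   _tukey(logs, "log") if posthoc else {},
                                   trail)
    elif force == "kruskal":
        trail.append(("forced_kruskal", 0.0))
    else:
        trail.append(("log_branch_blocked_nonpositive", 0.0))
    p = float(sps.kruskal(*groups).pvalue)
    pairs = {}
    if posthoc:
        for a, b in itertools.combinations(names, 2):
            key = tuple(sorted((a, b)))
            pairs[key] = float(sps.mannwhitneyu(
                values_by_group[key[0]], values_by_group[key[1]],
                alternative="two-sided").pvalue)
    return GroupComparison(variable, summaries, "kruskal", p,
                           "mannwhitney", pairs, trail)


def paired_change_test(before, after,
                       alpha: float = 0.05) -> tuple[float, str, list]:
    """Within-subject change: paired t test when the differences look
    normal (Shapiro-Wilk at 0.05), Wilcoxon signed-rank otherwise.

    Returns (p, test_used, trail)."""
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape:
        raise EstimationError("before/after must have equal length")
    d = after - before
    trail: list[tuple[str, float]] = []
    if np.allclose(d, 0.0):
        return 1.0, "degenerate", [("all_differences_zero", 1.0)]
    p_sw = float(sps.shapiro(d).pvalue)
    trail.append(("shapiro_differences", p_sw))
    if p_sw >= alpha:
        p = float(sps.ttest_rel(after, before).pvalue)
        return p, "paired_t", trail
    p = float(sps.wilcoxon(after, before).pvalue)
    return p, "wilcoxon", trail


@dataclass(frozen=True)
class OutcomeSpec:
    """Declarative description of one outcome variable.

    ``transform`` is one of auc, iauc, mean, cv, peak, time_to_peak,
    delta; ``baseline_time`` anchors iauc (the pre-insulin reference)
    and delta (the fasting reference)."""

    variable: str
    channel: str
    window: tuple[float, float]
    transform: str
    baseline_time: float | None = None

    def __post_init__(self) -> None:
        if self.transform not in ("auc", "iauc", "mean", "cv", "peak",
                                  "time_to_peak", "delta"):
            raise ValidationError(f"unknown transform {self.transform!r}")
        if self.transform in ("iauc", "delta") and self.baseline_time is None:
            raise ValidationError(f"{self.transform} needs a baseline_time")
        if self.baseline_time is not None \
                and self.baseline_time > self.window[0]:
            raise ValidationError("baseline_time must precede the window")

    def evaluate(self, series: SampledSeries) -> float:
        if self.transform == "auc":
            return auc_trapezoid(series, self.window)
        if self.transform == "iauc":
            return iauc(series, self.window, self.baseline_time)
        if self.transform == "mean":
            return window_stats(series, self.window)[0]
        if self.transform == "cv":
            return window_stats(series, self.window)[2]
        if self.transform == "peak":
            return peak_metrics(series, self.window)[0]
        if self.transform == "time_to_peak":
            return peak_metrics(series, self.window)[1]
        # delta: value at window end minus value at baseline
        return series.value_at(self.window[1]) - series.value_at(self.baseline_time)
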