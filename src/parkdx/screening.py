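"""Group screening: one-way ANOVA per biomarker and biomarker selection.

Each biomarker is screened for differences across the three diagnosis
groups with a classical fixed-effects one-way ANOVA. Two entry points are
provided: :func:`anova_oneway` takes individual-level values, while
:func:`anova_from_summary` computes the identical F statistic directly from
per-group (n, mean, sd) summaries — the form in which the study's group
statistics are published, which lets the printed F values be recomputed
without patient-level data. Biomarkers whose p-value falls below ``alpha``
are retained for the decision model; in the source study this screening
drops all five FA biomarkers and keeps the atrophy and SWI panels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .biomarkers import BIOMARKERS, CLASS_ORDER, Cohort


class DegenerateVarianceError(ValueError):
    """All values identical: the within-group variance is zero."""


@dataclass(frozen=True)
class GroupSummary:
    """Per-group sample size, mean and standard deviation."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"group size must be positive, got {self.n}")
        if self.sd < 0:
            raise ValueError(f"sd must be nonnegative, got {self.sd}")


@dataclass(frozen=True)
class AnovaResult:
    """One-way ANOVA F statistic with degrees of freedom and p-value."""

    f_value: float
    df_between: int
    df_within: int
    p_value: float

    @property
    def p_display(self) -> str:
        """Human-readable p: plain decimal, or an upper bound like ``<10^-4``."""
        return format_p(self.p_value)


def format_p(p: float) -> str:
    if p >= 0.001:
        return f"{p:.2f}"
    if p <= 0.0:
        return "<10^-16"
    return f"<10^-{int(math.floor(-math.log10(p)))}"


def anova_oneway(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """Fixed-effects one-way ANOVA on individual-level values."""
    if len(groups) < 2:
        raise ValueError(f"need >= 2 groups, got {len(groups)}")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for i, a in enumerate(arrays):
        if a.size < 2:
            raise ValueError(f"group {i} has fewer than 2 values")
    if all(np.ptp(a) == 0 for a in arrays) and len({a[0] for a in arrays}) == 1:
        raise DegenerateVarianceError("all values identical across all groups")
    if sum((a.size - 1) * a.var(ddof=1) for a in arrays) == 0:
        raise DegenerateVarianceError("zero pooled within-group variance")
    f, p = stats.f_oneway(*arrays)
    k = len(arrays)
    n_total = sum(a.size for a in arrays)
    return AnovaResult(f_value=float(f), df_between=k - 1,
                       df_within=n_total - k, p_value=float(p))


def anova_from_summary(summaries: Sequence[GroupSummary]) -> AnovaResult:
    """One-way ANOVA computed from per-group (n, mean, sd) summaries.

    F = [sum n_g (m_g - m)^2 / (k-1)] / [sum (n_g - 1) s_g^2 / (N-k)]
    with m the grand (size-weighted) mean. Identical to
    :func:`anova_oneway` applied to any dataset with these exact summaries.
    """
    if len(summaries) < 2:
        raise ValueError(f"need >= 2 summaries, got {len(summaries)}")
    n = np.array([s.n for s in summaries], dtype=float)
    m = np.array([s.mean for s in summaries])
    sd = np.array([s.sd for s in summaries])
    k = len(summaries)
    n_total = n.sum()
    ss_within = float(((n - 1) * sd**2).sum())
    if ss_within <= 0:
        raise DegenerateVarianceError("zero pooled within-group variance")
    grand = float((n * m).sum() / n_total)
    ss_between = float((n * (m - grand) ** 2).sum())
    df_b, df_w = k - 1, int(n_total) - k
    f = (ss_between / df_b) / (ss_within / df_w)
    return AnovaResult(f_value=f, df_between=df_b, df_within=df_w,
                       p_value=float(stats.f.sf(f, df_b, df_w)))


def group_summaries(cohort: Cohort, biomarker: str,
                    classes: Sequence[str] = CLASS_ORDER) -> List[GroupSummary]:
    """Exact per-class summaries of one biomarker (missing values skipped)."""
    out = []
    for c in classes:
        vals = np.array([p.values[biomarker] for p in cohort
                         if p.diagnosis == c and biomarker in p.values])
        if vals.size < 2:
            raise ValueError(f"class {c} has < 2 values for {biomarker}")
        out.append(GroupSummary(n=int(vals.size), mean=float(vals.mean()),
                                sd=float(vals.std(ddof=1))))
    return out


def screen_cohort(cohort: Cohort,
                  biomarkers: Sequence[str] = BIOMARKERS,
                  classes: Sequence[str] = CLASS_ORDER) -> Dict[str, AnovaResult]:
    """Per-biomarker one-way ANOVA across the diagnosis groups of a cohort."""
    results = {}
    for b in biomarkers:
        groups = [[p.values[b] for p in cohort
                   if p.diagnosis == c and b in p.values] for c in classes]
        results[b] = anova_oneway(groups)
    return results


def screen_summaries(
    marginals: Mapping[Tuple[str, str], Tuple[float, float]],
    group_sizes: Mapping[str, int],
    biomarkers: Sequence[str] = BIOMARKERS,
    classes: Sequence[str] = CLASS_ORDER,
) -> Dict[str, AnovaResult]:
    """Per-biomarker ANOVA from published (mean, sd) tables and group sizes."""
    results = {}
    for b in biomarkers:
        if not all((c, b) in marginals for c in classes):
            continue
        results[b] = anova_from_summary([
            GroupSummary(n=group_sizes[c], mean=marginals[(c, b)][0],
                         sd=marginals[(c, b)][1]) for c in classes])
    return results


def select_biomarkers(results: Mapping[str, AnovaResult],
                      alpha: float = 0.05) -> List[str]:
    """Biomarkers with p < alpha, in canonical order (atrophy, SWI, FA)."""
    if not 0 < alpha < 1 and alpha != 1.0:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    if not results:
        raise ValueError("empty results mapping")
    ordered = [b for b in BIOMARKERS if b in results]
    ordered += [b for b in results if b not in BIOMARKERS]
    return [b for b in ordered if results[b].p_value < alpha]


def mean_ordering(summaries: Sequence[GroupSummary],
                  classes: Sequence[str] = CLASS_ORDER) -> str:
    """Descriptive ordering of group means, e.g. ``"PSP > PD > MSA"``.

    Reported only descriptively when F is significant; no formal post-hoc
    test is performed.
    """
    order = sorted(range(len(summaries)), key=lambda i: -summaries[i].mean)
    return " > ".join(classes[i] for i in order)


def screening_report(
    results: Mapping[str, AnovaResult],
    summaries: Mapping[str, Sequence[GroupSummary]],
    alpha: float = 0.05,
    classes: Sequence[str] = CLASS_ORDER,
) -> pd.DataFrame:
    """Render a per-biomarker report: group mean (sd), F, p, ordering."""
    rows = []
    for b in [x for x in BIOMARKERS if x in results] + [
            x for x in results if x not in BIOMARKERS]:
        r = results[b]
        row: Dict[str, object] = {"biomarker": b}
        for c, s in zip(classes, summaries[b]):
            row[f"{c} mean (sd)"] = f"{s.mean:.3f} ({s.sd:.3f})"
        row["F"] = round(r.f_value, 3)
        row["p"] = r.p_display
        row["ordering"] = (mean_ordering(summaries[b], classes)
                           if r.p_value < alpha else "-")
        rows.append(row)
    return pd.DataFrame(rows)
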