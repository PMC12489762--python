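"""One-vs-rest diagnostic metrics and the class-balanced bootstrap.

Because the study groups are heavily imbalanced (38 PD / 25 MSA / 10 PSP),
plain resubstitution metrics are dominated by the majority class. The
balanced bootstrap draws an equal number of patients (default 10) with
replacement from each class, refits the chosen decision model on the
balanced sample, classifies that same sample, and records per-class
one-vs-rest sensitivity, specificity and accuracy. Repeated B times
(default 25,000) this yields a mean and 95% confidence interval per class
and metric, plus a running-mean trace for convergence checking.

Two interval methods are computed: the standard-error-of-the-mean interval
mean +/- 1.96 sd/sqrt(B) (primary; its width shrinks as 1/sqrt(B)) and the
2.5/97.5 percentile interval of the per-iteration metric distribution
(wider; describes per-resample spread rather than the mean's uncertainty).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .biomarkers import CLASS_ORDER, MSA, PD, PSP, Cohort
from .bayes import (
    ATROPHY_FEATURES, DEFAULT_FEATURES, SD_FLOOR_FRACTION,
)

METRICS: tuple[str, ...] = ("sensitivity", "specificity", "accuracy")

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class ConfusionMatrix:
    """Cross-tabulation of true vs predicted diagnosis labels."""

    classes: Tuple[str, ...]
    counts: np.ndarray  # (n_classes, n_classes), rows = true

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts,
                            index=[f"true {c}" for c in self.classes],
                            columns=[f"pred {c}" for c in self.classes])


@dataclass(frozen=True)
class MetricsTriple:
    """One-vs-rest sensitivity, specificity, accuracy (NaN = undefined)."""

    sensitivity: float
    specificity: float
    accuracy: float


def confusion(true_labels: Sequence[str], predicted_labels: Sequence[str],
              classes: Sequence[str] = CLASS_ORDER) -> ConfusionMatrix:
    """3x3 cross-tabulation; empty input yields an all-zero matrix."""
    if len(true_labels) != len(predicted_labels):
        raise ValueError(
            f"length mismatch: {len(true_labels)} true vs "
            f"{len(predicted_labels)} predicted")
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(true_labels, predicted_labels):
        if t not in index or p not in index:
            raise ValueError(f"unknown label in pair ({t!r}, {p!r})")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(classes=tuple(classes), counts=counts)


def one_vs_rest(cm: ConfusionMatrix, positive: str) -> MetricsTriple:
    """Metrics treating ``positive`` as positive and the pooled rest as negative.

    sensitivity = TP/(TP+FN); specificity = TN/(TN+FP);
    accuracy = (TP+TN)/total. An empty positive (or negative) margin flags
    the corresponding metric as undefined (NaN).
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    i = cm.classes.index(positive)
    tp = cm.counts[i, i]
    fn = cm.counts[i, :].sum() - tp
    fp = cm.counts[:, i].sum() - tp
    tn = cm.total - tp - fn - fp
    sens = tp / (tp + fn) if (tp + fn) > 0 else float("nan")
    spec = tn / (tn + fp) if (tn + fp) > 0 else float("nan")
    acc = (tp + tn) / cm.total
    return MetricsTriple(float(sens), float(spec), float(acc))


@dataclass
class BootstrapReport:
    """Per-class, per-metric mean and 95% intervals over B iterations.

    ``per_class[c][m]`` is ``(mean, ci_low, ci_high, sd_across_iterations)``
    using the SE-of-the-mean interval; ``per_class_percentile`` holds the
    2.5/97.5 percentile interval. ``trace`` contains running means recorded
    every ``trace_every`` iterations, shape (T, n_classes, n_metrics).
    """

    iterations: int
    group_size: int
    seed: int
    model_id: str
    classes: Tuple[str, ...]
    metrics: Tuple[str, ...]
    per_class: Dict[str, Dict[str, Tuple[float, float, float, float]]]
    per_class_percentile: Dict[str, Dict[str, Tuple[float, float]]]
    trace: np.ndarray
    trace_every: int
    n_undefined: Dict[str, Dict[str, int]] = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for c in self.classes:
            for m in self.metrics:
                mean, lo, hi, sd = self.per_class[c][m]
                plo, phi = self.per_class_percentile[c][m]
                rows.append({"class": c, "metric": m, "mean": mean,
                             "ci_low": lo, "ci_high": hi,
                             "sd_iterations": sd,
                             "pct_low": plo, "pct_high": phi})
        return pd.DataFrame(rows)


def _fit_gaussian_params(X: np.ndarray, y: np.ndarray,
                         class_codes: Sequence[int]) -> Tuple[np.ndarray, np.ndarray]:
    """Vectorised per-class mean/SD (ddof=1, NaN-aware) with pooled-SD floor."""
    k = len(class_codes)
    means = np.empty((k, X.shape[1]))
    sds = np.empty((k, X.shape[1]))
    for i, code in enumerate(class_codes):
        Xi = X[y == code]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            means[i] = np.nanmean(Xi, axis=0)
            sds[i] = np.nanstd(Xi, axis=0, ddof=1)
    pooled = np.sqrt(np.nanmean(sds**2, axis=0))
    floor = np.where(pooled > 0, SD_FLOOR_FRACTION * pooled, 1e-12)
    np.maximum(sds, floor, out=sds)
    return means, sds


def _log_densities(X: np.ndarray, means: np.ndarray,
                   sds: np.ndarray) -> np.ndarray:
    """Summed Gaussian log densities, (n, k); NaN features contribute 0."""
    z = (X[:, None, :] - means[None, :, :]) / sds[None, :, :]
    terms = -0.5 * z**2 - np.log(sds)[None, :, :] - 0.5 * _LOG_2PI
    return np.nansum(terms, axis=2)


def _classify_sample(X: np.ndarray, y: np.ndarray, model_id: str,
                     feat_idx: Mapping[str, np.ndarray]) -> np.ndarray:
    """Fit the chosen topology on (X, y) and classify X. Labels are codes
    0=PD, 1=MSA, 2=PSP; ties resolve to the lowest code (canonical order)."""
    if model_id == "I":
        means, sds = _fit_gaussian_params(X, y, (0, 1, 2))
        scores = _log_densities(X, means, sds)  # uniform priors cancel
        return np.argmax(scores, axis=1)
    # model II: PSP-vs-rest on atrophy, then MSA-vs-PD
    a = feat_idx["stage1"]
    s = feat_idx["stage2"]
    y1 = (y == 2).astype(int)  # 1 = PSP
    means1, sds1 = _fit_gaussian_params(X[:, a], y1, (0, 1))
    ld1 = _log_densities(X[:, a], means1, sds1)
    # p1 = P(PSP): column 1
    p1 = 1.0 / (1.0 + np.exp(np.clip(ld1[:, 0] - ld1[:, 1], -700, 700)))
    mask2 = y < 2
    means2, sds2 = _fit_gaussian_params(X[mask2][:, s], y[mask2], (1, 0))
    ld2 = _log_densities(X[:, s], means2, sds2)
    # p2 = P(MSA | not PSP): column 0 of (MSA, PD)
    p2 = 1.0 / (1.0 + np.exp(np.clip(ld2[:, 1] - ld2[:, 0], -700, 700)))
    post = np.column_stack([(1 - p1) * (1 - p2), (1 - p1) * p2, p1])
    return np.argmax(post, axis=1)


def _metrics_from_codes(y_true: np.ndarray, y_pred: np.ndarray,
                        k: int = 3) -> np.ndarray:
    """(k, 3) array of one-vs-rest (sensitivity, specificity, accuracy)."""
    out = np.empty((k, 3))
    n = y_true.size
    for c in range(k):
        pos = y_true == c
        ppos = y_pred == c
        tp = np.count_nonzero(pos & ppos)
        fn = np.count_nonzero(pos & ~ppos)
        fp = np.count_nonzero(~pos & ppos)
        tn = n - tp - fn - fp
        out[c, 0] = tp / (tp + fn) if (tp + fn) else np.nan
        out[c, 1] = tn / (tn + fp) if (tn + fp) else np.nan
        out[c, 2] = (tp + tn) / n
    return out


def bootstrap_evaluate(
    cohort: Cohort,
    model_id: str = "I",
    iterations: int = 25_000,
    group_size: int = 10,
    seed: int = 0,
    features: Sequence[str] = DEFAULT_FEATURES,
    stage2_features: Optional[Sequence[str]] = None,
    prior_mode: str = "uniform",
    resample_psp: bool = True,
    protocol: str = "resubstitution",
    trace_every: int = 100,
) -> BootstrapReport:
    """Class-balanced bootstrap evaluation of a decision-model topology.

    Each iteration draws ``group_size`` patients with replacement from each
    of PD, MSA and PSP (``resample_psp=False`` keeps the full PSP group
    fixed instead), fits the topology on the balanced sample with uniform
    priors, and evaluates on the same sample (``protocol="resubstitution"``)
    or on the out-of-bag patients (``protocol="out_of_bag"``). Fully
    deterministic given ``seed``.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if group_size < 2:
        raise ValueError("group_size must be >= 2 (per-class SDs need n >= 2)")
    if model_id not in ("I", "II"):
        raise ValueError(f"model_id must be 'I' or 'II', got {model_id!r}")
    if protocol not in ("resubstitution", "out_of_bag"):
        raise ValueError(f"unknown protocol {protocol!r}")
    if prior_mode != "uniform":
        raise ValueError("bootstrap evaluation supports uniform priors only")
    if stage2_features is None:
        stage2_features = features
    features = tuple(features)
    feat_idx = {
        "stage1": np.array([features.index(f) for f in ATROPHY_FEATURES
                            if f in features]),
        "stage2": np.array([features.index(f) for f in stage2_features
                            if f in features]),
    }
    if model_id == "II" and (feat_idx["stage1"].size == 0
                             or feat_idx["stage2"].size == 0):
        raise ValueError("model II requires atrophy and stage-2 features")

    per_class_X: List[np.ndarray] = []
    for c in CLASS_ORDER:
        sub = cohort.subset([c])
        if len(sub) < 2:
            raise ValueError(f"class {c} has fewer than 2 patients")
        Xc, _ = sub.feature_matrix(features)
        per_class_X.append(Xc)

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    metric_values = np.empty((iterations, 3, 3))
    for it in range(iterations):
        Xs, ys, oob_Xs, oob_ys = [], [], [], []
        for code, Xc in enumerate(per_class_X):
            n_c = Xc.shape[0]
            if code == 2 and not resample_psp:
                idx = np.arange(n_c)
            else:
                idx = rng.integers(0, n_c, size=group_size)
            Xs.append(Xc[idx])
            ys.append(np.full(idx.size, code))
            if protocol == "out_of_bag":
                mask = np.ones(n_c, dtype=bool)
                mask[np.unique(idx)] = False
                oob_Xs.append(Xc[mask])
                oob_ys.append(np.full(int(mask.sum()), code))
        X = np.vstack(Xs)
        y = np.concatenate(ys)
        if protocol == "resubstitution":
            pred = _classify_sample(X, y, model_id, feat_idx)
            metric_values[it] = _metrics_from_codes(y, pred)
        else:
            X_eval = np.vstack(oob_Xs)
            y_eval = np.concatenate(oob_ys)
            if y_eval.size == 0:
                metric_values[it] = np.nan
                continue
            if model_id == "I":
                means, sds = _fit_gaussian_params(X, y, (0, 1, 2))
                pred = np.argmax(_log_densities(X_eval, means, sds), axis=1)
            else:
                pred = _classify_oob_model2(X, y, X_eval, feat_idx)
            metric_values[it] = _metrics_from_codes(y_eval, pred)

    n_undefined = {
        c: {m: int(np.isnan(metric_values[:, ci, mi]).sum())
            for mi, m in enumerate(METRICS)}
        for ci, c in enumerate(CLASS_ORDER)}
    for c in CLASS_ORDER:
        for m in METRICS:
            if n_undefined[c][m]:
                warnings.warn(
                    f"{n_undefined[c][m]} iteration(s) had undefined {m} "
                    f"for class {c}; excluded from the average")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        means = np.nanmean(metric_values, axis=0)
        n_eff = np.sum(~np.isnan(metric_values), axis=0)
        sds = np.where(n_eff > 1,
                       np.nanstd(metric_values, axis=0, ddof=1), 0.0)
        half = 1.96 * sds / np.sqrt(np.maximum(n_eff, 1))
        plo = np.nanpercentile(metric_values, 2.5, axis=0)
        phi = np.nanpercentile(metric_values, 97.5, axis=0)

    # running-mean trace sampled every trace_every iterations
    ticks = np.arange(trace_every, iterations + 1, trace_every)
    if ticks.size == 0:
        ticks = np.array([iterations])
    cum = np.nancumsum(metric_values, axis=0)
    cnt = np.cumsum(~np.isnan(metric_values), axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        running = cum / np.maximum(cnt, 1)
    trace = running[ticks - 1]

    per_class = {c: {m: (float(means[ci, mi]),
                         float(means[ci, mi] - half[ci, mi]),
                         float(means[ci, mi] + half[ci, mi]),
                         float(sds[ci, mi]))
                     for mi, m in enumerate(METRICS)}
                 for ci, c in enumerate(CLASS_ORDER)}
    per_class_pct = {c: {m: (float(plo[ci, mi]), float(phi[ci, mi]))
                         for mi, m in enumerate(METRICS)}
                     for ci, c in enumerate(CLASS_ORDER)}
    return BootstrapReport(
        iterations=iterations, group_size=group_size, seed=seed,
        model_id=model_id, classes=tuple(CLASS_ORDER), metrics=METRICS,
        per_class=per_class, per_class_percentile=per_class_pct,
        trace=trace, trace_every=trace_every, n_undefined=n_undefined)


def _classify_oob_model2(X: np.ndarray, y: np.ndarray, X_eval: np.ndarray,
                         feat_idx: Mapping[str, np.ndarray]) -> np.ndarray:
    a, s = feat_idx["stage1"], feat_idx["stage2"]
    y1 = (y == 2).astype(int)
    means1, sds1 = _fit_gaussian_params(X[:, a], y1, (0, 1))
    ld1 = _log_densities(X_eval[:, a], means1, sds1)
    p1 = 1.0 / (1.0 + np.exp(np.clip(ld1[:, 0] - ld1[:, 1], -700, 700)))
    mask2 = y < 2
    means2, sds2 = _fit_gaussian_params(X[mask2][:, s], y[mask2], (1, 0))
    ld2 = _log_densities(X_eval[:, s], means2, sds2)
    p2 = 1.0 / (1.0 + np.exp(np.clip(ld2[:, 1] - ld2[:, 0], -700, 700)))
    post = np.column_stack([(1 - p1) * (1 - p2), (1 - p1) * p2, p1])
    return np.argmax(post, axis=1)


def convergence_trace(report: BootstrapReport,
                      burn_in_fraction: float = 0.6,
                      tolerance: float = 0.005) -> Dict[str, Dict[str, bool]]:
    """Check whether each running mean has stabilised.

    Returns, per class and metric, whether every running-mean sample after
    the burn-in point lies within ``tolerance`` of the final mean.
    """
    if not 0 <= burn_in_fraction < 1:
        raise ValueError("burn_in_fraction must be in [0, 1)")
    T = report.trace.shape[0]
    start = int(burn_in_fraction * T)
    out: Dict[str, Dict[str, bool]] = {}
    for ci, c in enumerate(report.classes):
        out[c] = {}
        for mi, m in enumerate(report.metrics):
            tail = report.trace[start:, ci, mi]
            final = report.trace[-1, ci, mi]
            out[c][m] = bool(np.all(np.abs(tail - final) <= tolerance))
    return out


def evaluation_report(reports: Sequence[BootstrapReport]) -> pd.DataFrame:
    """Render bootstrap results as 'mean (ci_low-ci_high)' per class/metric."""
    rows = []
    for rep in reports:
        for m in rep.metrics:
            row: Dict[str, object] = {"model": rep.model_id, "metric": m}
            for c in rep.classes:
                mean, lo, hi, _ = rep.per_class[c][m]
                row[c] = f"{mean:.3f} ({lo:.3f}-{hi:.3f})"
            rows.append(row)
    return pd.DataFrame(rows)


def plot_trace(report: BootstrapReport, path: str) -> None:
    """Save a running-mean convergence plot (one panel per metric)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = np.arange(1, report.trace.shape[0] + 1) * report.trace_every
    fig, axes = plt.subplots(1, len(report.metrics), figsize=(12, 3.5),
                             sharex=True)
    for mi, (ax, m) in enumerate(zip(np.atleast_1d(axes), report.metrics)):
        for ci, c in enumerate(report.classes):
            ax.plot(x, report.trace[:, ci, mi], label=c)
        ax.set_title(m)
        ax.set_xlabel("iteration")
    np.atleast_1d(axes)[0].set_ylabel("running mean")
    np.atleast_1d(axes)[0].legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
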