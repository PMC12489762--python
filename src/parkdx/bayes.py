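"""Gaussian Bayesian classification under two decision-model topologies.

The classifier is a diagonal-covariance ("naive") Gaussian Bayes model:
each class c has, per biomarker f, a Gaussian likelihood N(mu_cf, sigma_cf),
and the posterior over classes for a patient's panel x is

    P(c | x)  proportional to  prior(c) * prod_f N(x_f; mu_cf, sigma_cf),

computed in log space and normalised. Missing biomarkers are skipped, which
marginalises them out under the independence assumption. Per-class means and
SDs are the only published parameterisation of the study groups, so this is
the minimal model consistent with them.

Two topologies are provided:

* **Model I** — one three-class posterior over {PD, MSA, PSP} using all
  retained biomarkers at once.
* **Model II** — a two-stage decision tree: stage 1 separates PSP from the
  rest on the atrophy biomarkers (MRPI, MRPI2, pons/midbrain ratio);
  stage 2 separates MSA from PD on the SWI biomarkers plus, by default, the
  atrophy biomarkers. The combined posterior follows the chain rule:
  P(PSP) = p1, P(MSA) = (1-p1) p2, P(PD) = (1-p1)(1-p2).

Ties in the argmax are broken deterministically in the canonical class
order PD, MSA, PSP.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .biomarkers import (
    CLASS_ORDER, MSA, PD, PSP, BiomarkerPanel, Cohort,
)

#: Atrophy biomarkers (stage 1 of model II; decision rule on PSP atrophy).
ATROPHY_FEATURES: tuple[str, ...] = ("mrpi", "mrpi2", "t1_pm_ratio")
#: Iron-sensitive SWI biomarkers (MSA vs PD separation).
SWI_FEATURES: tuple[str, ...] = ("swi_put", "swi_stn", "swi_rn")
#: Default retained feature set after ANOVA screening (FA markers dropped).
DEFAULT_FEATURES: tuple[str, ...] = ATROPHY_FEATURES + SWI_FEATURES

#: Pooled-complement label used by the PSP-vs-rest stage of model II.
REST = "non-PSP"

#: Relative variance floor: per-feature SDs are floored at this fraction of
#: the feature's pooled SD so degenerate columns cannot produce infinities.
SD_FLOOR_FRACTION = 1e-6


class FittingError(ValueError):
    """A class lacks enough usable values to estimate its parameters."""


class InferenceError(ValueError):
    """A panel shares no features with the fitted model."""


@dataclass
class ClassConditionalModel:
    """Per-class, per-feature Gaussian parameters plus class priors."""

    classes: Tuple[str, ...]
    features: Tuple[str, ...]
    params: Dict[Tuple[str, str], Tuple[float, float]]
    priors: Dict[str, float]

    def __post_init__(self) -> None:
        for c in self.classes:
            for f in self.features:
                if (c, f) not in self.params:
                    raise ValueError(f"missing params for ({c}, {f})")
                if not self.params[(c, f)][1] > 0:
                    raise ValueError(f"non-positive sd for ({c}, {f})")
        total = sum(self.priors[c] for c in self.classes)
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"priors sum to {total}, not 1")


@dataclass
class PosteriorResult:
    """Normalised class probabilities, the argmax prediction, and topology id."""

    probabilities: Dict[str, float]
    predicted: str
    model_id: str

    def as_percentages(self, decimals: int = 2) -> Dict[str, float]:
        return {c: round(100.0 * p, decimals) for c, p in self.probabilities.items()}


def _argmax_with_tiebreak(classes: Sequence[str],
                          scores: Sequence[float]) -> str:
    best, best_score = classes[0], scores[0]
    for c, s in zip(classes[1:], scores[1:]):
        if s > best_score:
            best, best_score = c, s
    return best


def fit_class_conditionals(
    cohort: Cohort,
    features: Sequence[str] = DEFAULT_FEATURES,
    prior_mode: str = "uniform",
    classes: Sequence[str] = CLASS_ORDER,
) -> ClassConditionalModel:
    """Estimate per-class Gaussian parameters from a labeled cohort.

    Sample mean and sample SD (denominator n-1) per class and feature,
    skipping missing values; each SD is floored at ``SD_FLOOR_FRACTION``
    times the feature's pooled SD. Priors are uniform or proportional to
    class counts (``prior_mode="empirical"``).
    """
    if prior_mode not in ("uniform", "empirical"):
        raise ValueError(f"prior_mode must be 'uniform' or 'empirical', got {prior_mode!r}")
    per_class: Dict[Tuple[str, str], Tuple[float, float, int]] = {}
    for c in classes:
        for f in features:
            vals = np.array([p.values[f] for p in cohort
                             if p.diagnosis == c and f in p.values])
            if vals.size < 2:
                raise FittingError(
                    f"class {c} has {vals.size} usable value(s) for feature {f}")
            per_class[(c, f)] = (float(vals.mean()), float(vals.std(ddof=1)),
                                 int(vals.size))
    params: Dict[Tuple[str, str], Tuple[float, float]] = {}
    for f in features:
        stats_f = [per_class[(c, f)] for c in classes]
        pooled_var = (sum((n - 1) * sd**2 for _, sd, n in stats_f)
                      / max(sum(n - 1 for _, _, n in stats_f), 1))
        floor = SD_FLOOR_FRACTION * math.sqrt(pooled_var)
        if floor <= 0:
            floor = 1e-12  # every class degenerate in this feature
        for c in classes:
            mean, sd, _ = per_class[(c, f)]
            params[(c, f)] = (mean, max(sd, floor))
    counts = {c: sum(1 for p in cohort if p.diagnosis == c) for c in classes}
    if prior_mode == "empirical":
        total = sum(counts.values())
        priors = {c: counts[c] / total for c in classes}
    else:
        priors = {c: 1.0 / len(classes) for c in classes}
    return ClassConditionalModel(classes=tuple(classes), features=tuple(features),
                                 params=params, priors=priors)


def model_from_marginals(
    marginals: Mapping[Tuple[str, str], Tuple[float, float]],
    features: Sequence[str],
    classes: Sequence[str] = CLASS_ORDER,
    priors: Optional[Mapping[str, float]] = None,
) -> ClassConditionalModel:
    """Build a model directly from a published (class, feature) -> (mean, sd) table."""
    params = {(c, f): tuple(marginals[(c, f)]) for c in classes for f in features}
    if priors is None:
        priors = {c: 1.0 / len(classes) for c in classes}
    return ClassConditionalModel(tuple(classes), tuple(features),
                                 params, dict(priors))


def posterior(model: ClassConditionalModel, panel: BiomarkerPanel,
              model_id: str = "I") -> PosteriorResult:
    """Posterior class probabilities for one panel (log-space, normalised).

    Features absent from the panel are skipped (marginalised out).
    """
    present = [f for f in model.features if f in panel.values]
    if not present:
        raise InferenceError(
            f"panel {panel.patient_id} shares no features with the model "
            f"(model features: {list(model.features)})")
    logpost = np.empty(len(model.classes))
    for i, c in enumerate(model.classes):
        lp = math.log(model.priors[c])
        for f in present:
            mean, sd = model.params[(c, f)]
            z = (panel.values[f] - mean) / sd
            lp += -0.5 * z * z - math.log(sd) - 0.5 * math.log(2.0 * math.pi)
        logpost[i] = lp
    logpost -= logsumexp(logpost)
    probs = np.exp(logpost)
    probs /= probs.sum()
    probabilities = {c: float(p) for c, p in zip(model.classes, probs)}
    predicted = _argmax_with_tiebreak(model.classes, probs)
    return PosteriorResult(probabilities=probabilities, predicted=predicted,
                           model_id=model_id)


def classify_model1(model: ClassConditionalModel,
                    panel: BiomarkerPanel) -> PosteriorResult:
    """Model I: single three-class posterior over {PD, MSA, PSP}."""
    if set(model.classes) != set(CLASS_ORDER):
        raise ValueError(f"model I requires classes {CLASS_ORDER}, got {model.classes}")
    return posterior(model, panel, model_id="I")


def classify_model2(stage_psp: ClassConditionalModel,
                    stage_msa_pd: ClassConditionalModel,
                    panel: BiomarkerPanel) -> PosteriorResult:
    """Model II: PSP-vs-rest stage chained with an MSA-vs-PD stage.

    P(PSP) = p1; P(MSA) = (1-p1) p2; P(PD) = (1-p1)(1-p2), where p1 is the
    PSP probability from stage 1 and p2 the MSA probability from stage 2.
    """
    if PSP not in stage_psp.classes or len(stage_psp.classes) != 2:
        raise ValueError(f"stage 1 must be binary with PSP, got {stage_psp.classes}")
    if set(stage_msa_pd.classes) != {MSA, PD}:
        raise ValueError(f"stage 2 must be {{MSA, PD}}, got {stage_msa_pd.classes}")
    p1 = posterior(stage_psp, panel).probabilities[PSP]
    if p1 >= 1.0:
        p2 = 0.0  # stage 2 is unreachable; its value is irrelevant
    else:
        p2 = posterior(stage_msa_pd, panel).probabilities[MSA]
    probabilities = {PD: (1.0 - p1) * (1.0 - p2),
                     MSA: (1.0 - p1) * p2,
                     PSP: p1}
    predicted = _argmax_with_tiebreak(
        CLASS_ORDER, [probabilities[c] for c in CLASS_ORDER])
    return PosteriorResult(probabilities=probabilities, predicted=predicted,
                           model_id="II")


def fit_model2_stages(
    cohort: Cohort,
    stage1_features: Sequence[str] = ATROPHY_FEATURES,
    stage2_features: Sequence[str] = DEFAULT_FEATURES,
    prior_mode: str = "uniform",
) -> Tuple[ClassConditionalModel, ClassConditionalModel]:
    """Fit model II's two binary stages from a labeled cohort.

    Stage 1 pools PD and MSA into a ``non-PSP`` class over the atrophy
    biomarkers; stage 2 is fitted on PD and MSA patients only. Stage 2
    defaults to SWI plus atrophy features (the atrophy markers also carry
    some MSA-vs-PD signal).
    """
    pooled = Cohort(
        [BiomarkerPanel(p.patient_id,
                        PSP if p.diagnosis == PSP else None,
                        values=dict(p.values))
         for p in cohort if p.diagnosis is not None],
        provenance=cohort.provenance)
    # relabel the complement explicitly (bypass diagnosis vocabulary check)
    for p in pooled.panels:
        if p.diagnosis is None:
            p.diagnosis = REST
    stage1 = fit_class_conditionals(pooled, features=stage1_features,
                                    prior_mode=prior_mode, classes=(PSP, REST))
    stage2 = fit_class_conditionals(cohort.subset((MSA, PD)),
                                    features=stage2_features,
                                    prior_mode=prior_mode, classes=(MSA, PD))
    return stage1, stage2


def classify_cohort(
    cohort: Cohort,
    model_id: str = "I",
    features: Sequence[str] = DEFAULT_FEATURES,
    stage2_features: Optional[Sequence[str]] = None,
    prior_mode: str = "uniform",
    protocol: str = "resubstitution",
) -> pd.DataFrame:
    """Fit the chosen topology and classify every patient of a cohort.

    ``protocol="resubstitution"`` fits on the full cohort and classifies the
    same patients (the default evaluation protocol);
    ``protocol="leave_one_out"`` refits without each patient before
    classifying them. Returns a per-patient table: true label, per-class
    probabilities in percent (two decimals), prediction, topology id.
    """
    if model_id not in ("I", "II"):
        raise ValueError(f"model_id must be 'I' or 'II', got {model_id!r}")
    if protocol not in ("resubstitution", "leave_one_out"):
        raise ValueError(f"unknown protocol {protocol!r}")
    if stage2_features is None:
        stage2_features = features

    def _classify_with(train: Cohort, panel: BiomarkerPanel) -> PosteriorResult:
        if model_id == "I":
            model = fit_class_conditionals(train, features=features,
                                           prior_mode=prior_mode)
            return classify_model1(model, panel)
        s1, s2 = fit_model2_stages(train, stage1_features=ATROPHY_FEATURES,
                                   stage2_features=stage2_features,
                                   prior_mode=prior_mode)
        return classify_model2(s1, s2, panel)

    rows = []
    full_fit: Optional[Tuple] = None
    for idx, panel in enumerate(cohort):
        if protocol == "resubstitution":
            if full_fit is None:
                if model_id == "I":
                    full_fit = (fit_class_conditionals(
                        cohort, features=features, prior_mode=prior_mode),)
                else:
                    full_fit = fit_model2_stages(
                        cohort, stage1_features=ATROPHY_FEATURES,
                        stage2_features=stage2_features, prior_mode=prior_mode)
            result = (classify_model1(full_fit[0], panel) if model_id == "I"
                      else classify_model2(full_fit[0], full_fit[1], panel))
        else:
            train = Cohort([p for j, p in enumerate(cohort) if j != idx],
                           provenance=cohort.provenance)
            result = _classify_with(train, panel)
        pct = result.as_percentages()
        rows.append({
            "patient_id": panel.patient_id,
            "true": panel.diagnosis if panel.diagnosis else "",
            "MSA (%)": pct[MSA], "PD (%)": pct[PD], "PSP (%)": pct[PSP],
            "predicted": result.predicted,
            "model": result.model_id,
            "correct": (result.predicted == panel.diagnosis
                        if panel.diagnosis else ""),
        })
    return pd.DataFrame(rows)
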