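"""Robust within-group outlier flagging.

The source analysis identified outliers visually — patients far from the
rest of their own diagnosis group in at least one biomarker. This module
mechanises that judgement with a reproducible convention: per group and
biomarker, a robust z-score

    z = (x - median) / (1.4826 * MAD)

(the 1.4826 factor makes the median absolute deviation consistent with the
SD under normality), flagging |z| above a threshold (default 2.5). This is
an artifact convention, not a published criterion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .biomarkers import BIOMARKERS, CLASS_ORDER, Cohort

MAD_SCALE = 1.4826  # consistency factor vs the Gaussian SD


@dataclass(frozen=True)
class OutlierFlag:
    patient_id: str
    diagnosis: str
    biomarker: str
    robust_z: float
    direction: str  # "high" | "low"


def flag_outliers(cohort: Cohort, threshold: float = 2.5,
                  biomarkers: Sequence[str] = BIOMARKERS,
                  classes: Sequence[str] = CLASS_ORDER) -> List[OutlierFlag]:
    """Flag patients whose robust z exceeds ``threshold`` within their group.

    Groups with MAD = 0 (no spread) or fewer than 3 present values for a
    biomarker are skipped with a warning. Deterministic; flags are ordered
    by class, biomarker, then cohort order.
    """
    if not threshold > 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    flags: List[OutlierFlag] = []
    for c in classes:
        members = [p for p in cohort if p.diagnosis == c]
        for b in biomarkers:
            present = [(p.patient_id, p.values[b]) for p in members
                       if b in p.values]
            if len(present) < 3:
                warnings.warn(
                    f"group {c}, biomarker {b}: only {len(present)} value(s); skipped")
                continue
            vals = np.array([v for _, v in present])
            med = float(np.median(vals))
            mad = float(np.median(np.abs(vals - med)))
            if mad == 0:
                warnings.warn(
                    f"group {c}, biomarker {b}: zero MAD (no spread); skipped")
                continue
            z = (vals - med) / (MAD_SCALE * mad)
            for (pid, _), zi in zip(present, z):
                if abs(zi) > threshold:
                    flags.append(OutlierFlag(
                        patient_id=pid, diagnosis=c, biomarker=b,
                        robust_z=float(zi),
                        direction="high" if zi > 0 else "low"))
    return flags


def outlier_report(flags: Sequence[OutlierFlag],
                   classification: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    """Join outlier flags with per-patient posterior percentages.

    ``classification`` is the per-patient table produced by
    :func:`parkdx.bayes.classify_cohort`; when given, each flagged patient's
    posterior percentages, prediction and correctness are appended, yielding
    a per-outlier summary in the style of a case table.
    """
    rows = []
    for f in flags:
        rows.append({"patient_id": f.patient_id, "diagnosis": f.diagnosis,
                     "biomarker": f.biomarker,
                     "robust_z": round(f.robust_z, 2),
                     "direction": f.direction})
    df = pd.DataFrame(rows, columns=["patient_id", "diagnosis", "biomarker",
                                     "robust_z", "direction"])
    if classification is not None and not df.empty:
        df = df.merge(
            classification[["patient_id", "MSA (%)", "PD (%)", "PSP (%)",
                            "predicted", "correct"]],
            on="patient_id", how="left")
    return df
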