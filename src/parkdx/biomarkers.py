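"""Patient data model and biomarker arithmetic.

The feature space of the diagnostic pipeline is a panel of up to eleven
quantitative MRI biomarkers per patient:

* atrophy markers from T1-weighted imaging — the Magnetic Resonance
  Parkinsonian Index (MRPI), its third-ventricle-corrected variant (MRPI2)
  and the plain pons-to-midbrain area ratio;
* fractional anisotropy (FA) averages from diffusion tensor imaging in five
  regions (superior/middle cerebellar peduncles, cerebellum, subthalamic
  region, putamen), stored on the conventional x1000 reporting scale;
* susceptibility-weighted imaging (SWI) signal in putamen, subthalamic
  region and red nucleus, normalised to white-matter signal (values below 1
  indicate increased mineralisation / iron deposition).

This module holds the typed containers (measurements, panels, cohorts), the
arithmetic that derives each biomarker from raw geometric and signal
measurements, and delimited-text I/O for cohorts.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Union

import numpy as np
import pandas as pd

# --------------------------------------------------------------------------
# Diagnosis labels
# --------------------------------------------------------------------------

PD = "PD"
MSA = "MSA"
PSP = "PSP"

#: Canonical class order; also the deterministic tie-break order for argmax.
CLASS_ORDER: tuple[str, ...] = (PD, MSA, PSP)

#: Recognised MSA subtypes (parkinsonian, cerebellar, unclassified). All
#: collapse to MSA for analysis.
MSA_SUBTYPES: tuple[str, ...] = ("MSA-P", "MSA-C", "MSA-u")

#: Canonical biomarker order used for feature selection and reporting:
#: atrophy, then SWI, then FA.
BIOMARKERS: tuple[str, ...] = (
    "mrpi",
    "mrpi2",
    "t1_pm_ratio",
    "swi_put",
    "swi_stn",
    "swi_rn",
    "fa_scp",
    "fa_cb",
    "fa_mcp",
    "fa_stn",
    "fa_put",
)

#: Ratio-valued biomarkers: strictly positive when present.
RATIO_BIOMARKERS: tuple[str, ...] = (
    "mrpi", "mrpi2", "t1_pm_ratio", "swi_put", "swi_stn", "swi_rn",
)

#: FA biomarkers: nonnegative, stored on the x1000 printed scale.
FA_BIOMARKERS: tuple[str, ...] = ("fa_scp", "fa_cb", "fa_mcp", "fa_stn", "fa_put")

#: Column layout of the tabular cohort format.
COHORT_COLUMNS: tuple[str, ...] = (
    "patient_id", "diagnosis", "subtype",
    "mrpi", "mrpi2", "t1_pm_ratio",
    "fa_scp", "fa_cb", "fa_mcp", "fa_stn", "fa_put",
    "swi_put", "swi_stn", "swi_rn",
)


class InvalidMeasurementError(ValueError):
    """A raw measurement violates its positivity/validity constraint."""

    def __init__(self, fieldname: str, value: float, constraint: str = "> 0"):
        self.fieldname = fieldname
        self.value = value
        super().__init__(f"invalid measurement {fieldname}={value!r}: must be {constraint}")


class EmptyRegionError(ValueError):
    """A region-of-interest mask selects no voxels."""


class CohortFormatError(ValueError):
    """A cohort table violates the expected schema or its invariants."""


def parse_diagnosis(label: Optional[str]) -> tuple[Optional[str], Optional[str]]:
    """Normalise a diagnosis string to ``(class, subtype)``.

    ``"MSA-P"/"MSA-C"/"MSA-u"`` collapse to class ``MSA`` with the subtype
    retained; ``None``/empty means unlabeled.
    """
    if label is None or (isinstance(label, float) and math.isnan(label)) or label == "":
        return None, None
    label = str(label)
    if label in CLASS_ORDER:
        return label, None
    if label in MSA_SUBTYPES:
        return MSA, label
    raise CohortFormatError(f"unknown diagnosis label {label!r}")


# --------------------------------------------------------------------------
# Raw measurement containers
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class GeometricMeasurements:
    """Midsagittal/axial geometry entering the atrophy biomarkers.

    Areas in mm^2, widths in mm; all strictly positive.
    """

    pons_area: float
    midbrain_area: float
    mcp_width_left: float
    mcp_width_right: float
    scp_width_left: float
    scp_width_right: float
    third_ventricle_width: float
    frontal_horns_width: float

    def __post_init__(self) -> None:
        for f in dc_fields(self):
            v = getattr(self, f.name)
            if not (v > 0) or not math.isfinite(v):
                raise InvalidMeasurementError(f.name, v)


@dataclass(frozen=True)
class SignalMeasurements:
    """Region-averaged SWI signal and FA values.

    SWI means are in arbitrary scanner units; ``swi_wm_mean`` (the
    white-matter reference) must be positive. FA values are nonnegative and
    stored on the x1000 reporting scale by default (see ``fa_scale`` in
    :func:`derive_panel`).
    """

    swi_put_mean: float = math.nan
    swi_stn_mean: float = math.nan
    swi_rn_mean: float = math.nan
    swi_wm_mean: float = math.nan
    fa_scp: float = math.nan
    fa_cb: float = math.nan
    fa_mcp: float = math.nan
    fa_stn: float = math.nan
    fa_put: float = math.nan

    def __post_init__(self) -> None:
        for f in dc_fields(self):
            v = getattr(self, f.name)
            if math.isnan(v):
                continue
            if f.name == "swi_wm_mean":
                if not v > 0:
                    raise InvalidMeasurementError(f.name, v)
            elif v < 0:
                raise InvalidMeasurementError(f.name, v, ">= 0")


# --------------------------------------------------------------------------
# Biomarker arithmetic
# --------------------------------------------------------------------------


def compute_pm_ratio(g: GeometricMeasurements) -> float:
    """Pons-to-midbrain area ratio; elevated in PSP (midbrain atrophy)."""
    if not g.midbrain_area > 0:
        raise InvalidMeasurementError("midbrain_area", g.midbrain_area)
    return g.pons_area / g.midbrain_area


def compute_mrpi(g: GeometricMeasurements) -> float:
    """Magnetic Resonance Parkinsonian Index.

    (pons area / midbrain area) x (mean MCP width / mean SCP width), the
    mean being the arithmetic mean of the left and right widths.
    """
    scp_mean = 0.5 * (g.scp_width_left + g.scp_width_right)
    if not scp_mean > 0:
        raise InvalidMeasurementError("scp_width", scp_mean)
    mcp_mean = 0.5 * (g.mcp_width_left + g.mcp_width_right)
    return compute_pm_ratio(g) * (mcp_mean / scp_mean)


def compute_mrpi2(mrpi: float, g: GeometricMeasurements) -> float:
    """MRPI scaled by the third-ventricle to frontal-horns width ratio."""
    if not g.frontal_horns_width > 0:
        raise InvalidMeasurementError("frontal_horns_width", g.frontal_horns_width)
    return mrpi * g.third_ventricle_width / g.frontal_horns_width


def normalize_swi(roi_mean: float, wm_mean: float) -> float:
    """SWI region mean normalised to white-matter mean.

    Values below 1 mean the region is darker than white matter, i.e. more
    mineralised (iron-rich).
    """
    if not wm_mean > 0:
        raise InvalidMeasurementError("swi_wm_mean", wm_mean)
    if roi_mean < 0:
        raise InvalidMeasurementError("roi_mean", roi_mean, ">= 0")
    return roi_mean / wm_mean


def mean_in_mask(values: Sequence[float], mask: Sequence[bool]) -> float:
    """Arithmetic mean of ``values`` where ``mask`` is true.

    This is the region-averaging primitive behind the FA biomarkers.
    """
    v = np.asarray(values, dtype=float)
    m = np.asarray(mask, dtype=bool)
    if v.shape != m.shape:
        raise ValueError(f"shape mismatch: values {v.shape} vs mask {m.shape}")
    if not m.any():
        raise EmptyRegionError("mask selects no elements")
    return float(v[m].mean())


# --------------------------------------------------------------------------
# Panels and cohorts
# --------------------------------------------------------------------------


@dataclass
class BiomarkerPanel:
    """One patient's labeled biomarker vector.

    ``values`` maps biomarker name -> value; a missing biomarker is simply
    absent from the mapping (never encoded as zero: zero is a legal-looking
    but wrong value for a ratio).
    """

    patient_id: str
    diagnosis: Optional[str] = None
    subtype: Optional[str] = None
    values: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.diagnosis is not None and self.diagnosis not in CLASS_ORDER:
            self.diagnosis, self.subtype = parse_diagnosis(self.diagnosis)
        if self.subtype is not None:
            if self.diagnosis != MSA:
                raise CohortFormatError(
                    f"patient {self.patient_id}: subtype {self.subtype!r} "
                    f"requires diagnosis MSA, got {self.diagnosis!r}")
            if self.subtype not in MSA_SUBTYPES:
                raise CohortFormatError(
                    f"patient {self.patient_id}: unknown MSA subtype {self.subtype!r}")
        for name, v in self.values.items():
            if name not in BIOMARKERS:
                raise CohortFormatError(
                    f"patient {self.patient_id}: unknown biomarker {name!r}")
            if not math.isfinite(v):
                raise CohortFormatError(
                    f"patient {self.patient_id}: non-finite {name}={v!r}")
            if name in RATIO_BIOMARKERS and not v > 0:
                raise InvalidMeasurementError(name, v)
            if name in FA_BIOMARKERS and v < 0:
                raise InvalidMeasurementError(name, v, ">= 0")

    def get(self, name: str) -> Optional[float]:
        return self.values.get(name)


def derive_panel(
    patient_id: str,
    geometric: Optional[GeometricMeasurements] = None,
    signal: Optional[SignalMeasurements] = None,
    diagnosis: Optional[str] = None,
    subtype: Optional[str] = None,
    fa_scale: str = "printed",
) -> BiomarkerPanel:
    """Derive a biomarker panel from raw measurements.

    ``fa_scale="printed"`` takes FA values already on the x1000 scale;
    ``"native"`` accepts FA in [0, 1] and rescales by 1000.
    """
    if fa_scale not in ("printed", "native"):
        raise ValueError(f"fa_scale must be 'printed' or 'native', got {fa_scale!r}")
    values: Dict[str, float] = {}
    if geometric is not None:
        mrpi = compute_mrpi(geometric)
        values["mrpi"] = mrpi
        values["mrpi2"] = compute_mrpi2(mrpi, geometric)
        values["t1_pm_ratio"] = compute_pm_ratio(geometric)
    if signal is not None:
        if not math.isnan(signal.swi_wm_mean):
            for roi in ("put", "stn", "rn"):
                roi_mean = getattr(signal, f"swi_{roi}_mean")
                if not math.isnan(roi_mean):
                    values[f"swi_{roi}"] = normalize_swi(roi_mean, signal.swi_wm_mean)
        scale = 1000.0 if fa_scale == "native" else 1.0
        for name in FA_BIOMARKERS:
            v = getattr(signal, name)
            if not math.isnan(v):
                values[name] = v * scale
    return BiomarkerPanel(patient_id=patient_id, diagnosis=diagnosis,
                          subtype=subtype, values=values)


@dataclass
class Cohort:
    """An ordered collection of patient panels with provenance metadata."""

    panels: List[BiomarkerPanel]
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [p.patient_id for p in self.panels]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortFormatError(f"duplicate patient_id(s): {dupes}")

    def __len__(self) -> int:
        return len(self.panels)

    def __iter__(self):
        return iter(self.panels)

    def labels(self) -> List[Optional[str]]:
        return [p.diagnosis for p in self.panels]

    def subset(self, classes: Iterable[str]) -> "Cohort":
        keep = set(classes)
        return Cohort([p for p in self.panels if p.diagnosis in keep],
                      provenance=self.provenance)

    def class_counts(self) -> Dict[str, int]:
        counts: Dict[str, int] = {}
        for p in self.panels:
            if p.diagnosis is not None:
                counts[p.diagnosis] = counts.get(p.diagnosis, 0) + 1
        return counts

    def feature_matrix(
        self, features: Sequence[str]
    ) -> tuple[np.ndarray, List[Optional[str]]]:
        """Return an ``(n_patients, n_features)`` array (NaN = missing) and labels."""
        X = np.full((len(self.panels), len(features)), np.nan)
        for i, p in enumerate(self.panels):
            for j, f in enumerate(features):
                v = p.values.get(f)
                if v is not None:
                    X[i, j] = v
        return X, self.labels()

    # -- tabular I/O --------------------------------------------------------

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for p in self.panels:
            row: Dict[str, object] = {
                "patient_id": p.patient_id,
                "diagnosis": p.diagnosis if p.diagnosis is not None else "",
                "subtype": p.subtype if p.subtype is not None else "",
            }
            for b in BIOMARKERS:
                row[b] = p.values.get(b, np.nan)
            rows.append(row)
        return pd.DataFrame(rows, columns=list(COHORT_COLUMNS))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, provenance: str = "") -> "Cohort":
        missing = [c for c in ("patient_id", "diagnosis") if c not in df.columns]
        if missing:
            raise CohortFormatError(f"missing required column(s): {missing}")
        panels = []
        for _, row in df.iterrows():
            diagnosis, subtype = parse_diagnosis(row.get("diagnosis"))
            raw_sub = row.get("subtype")
            if subtype is None and isinstance(raw_sub, str) and raw_sub:
                subtype = raw_sub
            values = {}
            for b in BIOMARKERS:
                if b in df.columns:
                    v = row[b]
                    if v is not None and not (isinstance(v, float) and math.isnan(v)) and v != "":
                        values[b] = float(v)
            panels.append(BiomarkerPanel(patient_id=str(row["patient_id"]),
                                         diagnosis=diagnosis, subtype=subtype,
                                         values=values))
        return cls(panels, provenance=provenance)

    def write_csv(self, path: Union[str, Path, io.TextIOBase]) -> None:
        # repr-precision floats so a write/read round-trip is bit-exact
        df = self.to_dataframe()
        df.to_csv(path, index=False, float_format=None)

    @classmethod
    def read_csv(cls, path: Union[str, Path, io.TextIOBase],
                 provenance: Optional[str] = None) -> "Cohort":
        try:
            # round_trip parser: values written at repr precision come back
            # bit-exact
            df = pd.read_csv(path, float_precision="round_trip")
        except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
            raise CohortFormatError(f"unreadable cohort table: {exc}") from exc
        return cls.from_dataframe(
            df, provenance=provenance if provenance is not None else f"file:{path}")


#: Columns of the raw-measurement schema (second input schema).
RAW_GEOMETRIC_COLUMNS = tuple(f.name for f in dc_fields(GeometricMeasurements))
RAW_SIGNAL_COLUMNS = tuple(f.name for f in dc_fields(SignalMeasurements))


def derive_cohort_from_raw(df: pd.DataFrame, fa_scale: str = "printed",
                           provenance: str = "raw-measurements") -> Cohort:
    """Build a derived-biomarker cohort from a raw measurement table.

    The table must contain ``patient_id``; ``diagnosis``/``subtype`` are
    optional, as is any subset of the geometric and signal columns. Rows
    with all geometric columns present get the three atrophy biomarkers;
    SWI/FA columns are used where present.
    """
    if "patient_id" not in df.columns:
        raise CohortFormatError("missing required column(s): ['patient_id']")
    have_geom = all(c in df.columns for c in RAW_GEOMETRIC_COLUMNS)
    panels = []
    for _, row in df.iterrows():
        geom = None
        if have_geom and all(not math.isnan(float(row[c])) for c in RAW_GEOMETRIC_COLUMNS):
            geom = GeometricMeasurements(**{c: float(row[c]) for c in RAW_GEOMETRIC_COLUMNS})
        sig_kwargs = {c: float(row[c]) for c in RAW_SIGNAL_COLUMNS
                      if c in df.columns and not math.isnan(float(row[c]))}
        signal = SignalMeasurements(**sig_kwargs) if sig_kwargs else None
        diagnosis, subtype = parse_diagnosis(row.get("diagnosis"))
        panels.append(derive_panel(str(row["patient_id"]), geom, signal,
                                   diagnosis=diagnosis, subtype=subtype,
                                   fa_scale=fa_scale))
    return Cohort(panels, provenance=provenance)
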