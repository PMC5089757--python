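"""Domain types and file I/O for 4D MRA / SWI cohort analysis.

The central objects are a time-resolved non-contrast MR angiography series
(:class:`Series4D`, typically 12 frames at 60 ms per frame), per-voxel signal
curves sampled from it (:class:`SignalCurve`), the four-parameter linear
curve alignment (:class:`LinearTransform`), the smooth B-spline reference
inflow curve (:class:`ReferenceCurve`), and the patient cohort table
(:class:`PatientRecord` / :class:`CohortTable`) carrying SWI venous-contrast
scores, global time-to-peak (TTP) values and clinical chemistry.

Volumes are exchanged as NIfTI-1, cohort tables as UTF-8 CSV with ``n/a`` or
empty cells for missing values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterator, Optional, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

from .errors import DimensionalityError, ValidationError

__all__ = [
    "AcquisitionSpec",
    "Series4D",
    "SignalCurve",
    "LinearTransform",
    "ReferenceCurve",
    "VesselMask",
    "TTPMap",
    "PatientRecord",
    "CohortTable",
    "read_series4d",
    "write_series4d",
    "read_cohort_csv",
    "write_cohort_csv",
    "load_hus_cohort",
    "load_hus_cohort_excluded",
]


# --------------------------------------------------------------------------
# acquisition / image types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AcquisitionSpec:
    """Temporal sampling of a 4D MRA series.

    The default (12 frames, 60 ms per frame) matches a 1.5T spin-labeling
    inflow protocol; the frame axis is 1-based, so frame times are
    ``1..n_frames`` in frame units.
    """

    n_frames: int = 12
    frame_duration_ms: float = 60.0

    def __post_init__(self):
        if self.n_frames < 2:
            raise ValidationError(f"n_frames must be >= 2, got {self.n_frames}")
        if not (self.frame_duration_ms > 0):
            raise ValidationError("frame_duration_ms must be positive")

    @property
    def frame_times(self) -> np.ndarray:
        """1-based frame positions, in frame units."""
        return np.arange(1, self.n_frames + 1, dtype=float)


@dataclass
class Series4D:
    """A 4D MRA image series indexed ``(x, y, z, t)``."""

    data: np.ndarray
    spec: AcquisitionSpec = field(default_factory=AcquisitionSpec)
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise DimensionalityError(
                f"Series4D requires a 4D array, got {self.data.ndim}D"
            )
        if self.data.shape[3] != self.spec.n_frames:
            raise ValidationError(
                f"t-extent {self.data.shape[3]} != spec.n_frames {self.spec.n_frames}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("Series4D intensities must be finite")
        if np.any(self.data < 0):
            raise ValidationError("Series4D intensities must be >= 0")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValidationError("voxel sizes must be positive")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def curve_at(self, x: int, y: int, z: int) -> "SignalCurve":
        """Time course of a single voxel."""
        return SignalCurve(self.data[x, y, z, :], voxel=(x, y, z))


@dataclass
class SignalCurve:
    """One voxel's intensity-versus-frame series (frame axis 1..n)."""

    values: np.ndarray
    voxel: Optional[tuple[int, int, int]] = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size < 2:
            raise ValidationError("SignalCurve needs at least 2 samples")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("SignalCurve values must be finite")

    @property
    def n_frames(self) -> int:
        return self.values.size

    @property
    def frame_axis(self) -> np.ndarray:
        return np.arange(1, self.values.size + 1, dtype=float)

    def is_flat(self, rtol: float = 1e-12) -> bool:
        v = self.values
        return float(np.ptp(v)) <= rtol * max(1.0, float(np.max(np.abs(v))))


@dataclass(frozen=True)
class LinearTransform:
    """Four-parameter curve alignment: shift/scale in time and magnitude.

    Applying the transform to a curve ``c`` yields::

        c'(t) = mag_scale * c(time_scale * t + time_shift) + mag_shift

    so a feature of ``c`` at position ``t0`` (e.g. its peak) appears in the
    transformed curve at ``(t0 - time_shift) / time_scale``.
    """

    time_shift: float = 0.0
    time_scale: float = 1.0
    mag_shift: float = 0.0
    mag_scale: float = 1.0

    def __post_init__(self):
        if not (self.time_scale > 0):
            raise ValidationError("time_scale must be positive")
        if not (self.mag_scale > 0):
            raise ValidationError("mag_scale must be positive")

    @classmethod
    def identity(cls) -> "LinearTransform":
        return cls()

    def invert(self) -> "LinearTransform":
        """Transform undoing this one (compose(T, invert(T)) == identity)."""
        a, b = self.time_scale, self.time_shift
        s, m = self.mag_scale, self.mag_shift
        return LinearTransform(
            time_shift=-b / a, time_scale=1.0 / a,
            mag_shift=-m / s, mag_scale=1.0 / s,
        )

    def compose(self, inner: "LinearTransform") -> "LinearTransform":
        """Transform equivalent to applying ``inner`` first, then ``self``."""
        a1, b1, s1, m1 = (inner.time_scale, inner.time_shift,
                          inner.mag_scale, inner.mag_shift)
        a2, b2, s2, m2 = (self.time_scale, self.time_shift,
                          self.mag_scale, self.mag_shift)
        # self applied to (inner applied to c):
        # c''(t) = s2 * c'(a2 t + b2) + m2,  c'(u) = s1 * c(a1 u + b1) + m1
        return LinearTransform(
            time_shift=a1 * b2 + b1, time_scale=a1 * a2,
            mag_shift=s2 * m1 + m2, mag_scale=s1 * s2,
        )

    def map_peak_time(self, t: float) -> float:
        """Where a feature of the source curve at time ``t`` lands after
        transformation: ``(t - time_shift) / time_scale``."""
        return (t - self.time_shift) / self.time_scale

    def transform_samples(
        self, times: np.ndarray, values: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """Map discrete samples ``(t_k, v_k)`` of the source curve into the
        transformed curve's coordinates."""
        times = np.asarray(times, dtype=float)
        values = np.asarray(values, dtype=float)
        return ((times - self.time_shift) / self.time_scale,
                self.mag_scale * values + self.mag_shift)

    def as_array(self) -> np.ndarray:
        return np.array([self.time_shift, self.time_scale,
                         self.mag_shift, self.mag_scale])


@dataclass
class ReferenceCurve:
    """Smooth mean inflow curve (cubic B-spline) with its time-to-peak.

    ``support`` is the closed frame interval on which the curve is defined;
    evaluation outside the fitted domain uses constant (boundary-value)
    extension. ``ttp`` is the fractional-frame argmax over the support;
    ``ttp_at_boundary`` flags maxima attained at a support endpoint.
    """

    spline: BSpline
    support: tuple[float, float]
    ttp: float = float("nan")
    ttp_at_boundary: bool = False

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        lo, hi = self.spline.t[self.spline.k], self.spline.t[-self.spline.k - 1]
        return self.spline(np.clip(t, lo, hi))

    @property
    def n_frames(self) -> int:
        return int(round(self.support[1]))

    def sample_times(self) -> np.ndarray:
        """Integer frame positions inside the support."""
        lo, hi = self.support
        return np.arange(math.ceil(lo - 1e-9), math.floor(hi + 1e-9) + 1, dtype=float)


@dataclass
class VesselMask:
    """Boolean cerebrovascular segmentation aligned with a series' grid."""

    mask: np.ndarray

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise DimensionalityError("VesselMask must be 3D")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def coordinates(self) -> np.ndarray:
        """(n, 3) array of masked voxel indices in C order (deterministic)."""
        return np.argwhere(self.mask)


@dataclass
class TTPMap:
    """Per-voxel time-to-peak in frames; NaN marks undefined voxels."""

    values: np.ndarray
    mask: VesselMask

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.mask.mask.shape:
            raise ValidationError("TTPMap shape must match its mask")

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.values) & self.mask.mask

    def defined_values(self) -> np.ndarray:
        return self.values[self.defined]


# --------------------------------------------------------------------------
# cohort types
# --------------------------------------------------------------------------

VALID_MRI_CODES = frozenset({0, 1, 2, 3, 4, 6, 7})
VALID_SWI_SCORES = frozenset({1, 2, 3, 4})


@dataclass
class PatientRecord:
    """One patient's demographics, imaging read-outs and chemistry.

    ``mri_signal_code`` encodes conventional-MRI signal changes (0 = normal,
    1 = thalamus, 2 = pons, 3 = centrum semiovale, 4 = corpus callosum,
    6 = combination, 7 = other). ``swi_score`` is the ordinal venous-contrast
    score 1-4; ``ttp_frames`` the global 4D MRA time-to-peak. Any field typed
    Optional may be missing (None); statistics drop incomplete pairs pairwise.
    """

    patient_id: str
    sex: str
    age_years: float
    anesthesia: bool = False
    days_symptom_to_mri: Optional[int] = None
    mri_signal_code: Optional[int] = None
    etco2_mmHg: Optional[float] = None
    swi_score: Optional[int] = None
    ttp_frames: Optional[float] = None
    hemoglobin_g_dl: Optional[float] = None
    hematocrit_pct: Optional[float] = None
    creatinine: Optional[float] = None
    urea: Optional[float] = None
    exclusion_reason: Optional[str] = None

    def __post_init__(self):
        if self.sex not in ("m", "f"):
            raise ValidationError(
                f"patient {self.patient_id}: sex must be 'm' or 'f', got {self.sex!r}"
            )
        if self.age_years < 0:
            raise ValidationError(f"patient {self.patient_id}: negative age")
        if self.swi_score is not None and self.swi_score not in VALID_SWI_SCORES:
            raise ValidationError(
                f"patient {self.patient_id}: swi_score {self.swi_score} "
                "outside the 1-4 venous-contrast scale"
            )
        if (self.mri_signal_code is not None
                and self.mri_signal_code not in VALID_MRI_CODES):
            raise ValidationError(
                f"patient {self.patient_id}: mri_signal_code "
                f"{self.mri_signal_code} not in {sorted(VALID_MRI_CODES)}"
            )
        if self.ttp_frames is not None and self.ttp_frames <= 0:
            raise ValidationError(f"patient {self.patient_id}: nonpositive TTP")
        if self.etco2_mmHg is not None and self.etco2_mmHg <= 0:
            raise ValidationError(f"patient {self.patient_id}: nonpositive etCO2")
        for name in ("hemoglobin_g_dl", "hematocrit_pct", "creatinine", "urea"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValidationError(f"patient {self.patient_id}: negative {name}")
        if self.days_symptom_to_mri is not None and self.days_symptom_to_mri < 0:
            raise ValidationError(f"patient {self.patient_id}: negative days-to-MRI")

    @property
    def mri_abnormal(self) -> Optional[bool]:
        """Conventional MRI abnormal (signal code != 0); None if code missing."""
        if self.mri_signal_code is None:
            return None
        return self.mri_signal_code != 0


_RECORD_COLUMNS = [
    "patient_id", "sex", "age_years", "days_symptom_to_mri", "mri_signal_code",
    "etco2_mmHg", "swi_score", "ttp_frames", "hemoglobin_g_dl",
    "hematocrit_pct", "creatinine", "urea", "anesthesia", "exclusion_reason",
]


class CohortTable:
    """Ordered collection of :class:`PatientRecord` with unique IDs."""

    def __init__(self, records: Sequence[PatientRecord]):
        records = list(records)
        seen = set()
        for rec in records:
            if rec.patient_id in seen:
                raise ValidationError(f"duplicate patient_id {rec.patient_id!r}")
            seen.add(rec.patient_id)
        self.records = records

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self.records)

    def __getitem__(self, patient_id: str) -> PatientRecord:
        for rec in self.records:
            if rec.patient_id == str(patient_id):
                return rec
        raise KeyError(patient_id)

    def __eq__(self, other) -> bool:
        return (isinstance(other, CohortTable)
                and self.records == other.records)

    def column(self, name: str) -> np.ndarray:
        """Numeric column with NaN for missing values."""
        out = np.empty(len(self.records))
        for i, rec in enumerate(self.records):
            v = getattr(rec, name)
            out[i] = np.nan if v is None else float(v)
        return out

    def flag(self, name: str) -> np.ndarray:
        """Boolean column (``anesthesia`` or ``mri_abnormal``); missing -> False."""
        out = np.zeros(len(self.records), dtype=bool)
        for i, rec in enumerate(self.records):
            v = getattr(rec, name)
            out[i] = bool(v) if v is not None else False
        return out

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for rec in self.records:
            rows.append({c: getattr(rec, c) for c in _RECORD_COLUMNS})
        return pd.DataFrame(rows, columns=_RECORD_COLUMNS)

    def with_clinical(self, clinical: "CohortTable") -> "CohortTable":
        """Merge chemistry columns from a clinical table by patient ID."""
        merged = []
        for rec in self.records:
            try:
                cl = clinical[rec.patient_id]
            except KeyError:
                merged.append(rec)
                continue
            merged.append(replace(
                rec,
                hemoglobin_g_dl=cl.hemoglobin_g_dl,
                hematocrit_pct=cl.hematocrit_pct,
                creatinine=cl.creatinine,
                urea=cl.urea,
            ))
        return CohortTable(merged)


# --------------------------------------------------------------------------
# NIfTI I/O
# --------------------------------------------------------------------------

_TIME_UNIT_TO_MS = {"sec": 1000.0, "msec": 1.0, "usec": 1e-3}


def read_series4d(path) -> Series4D:
    """Read a 4D NIfTI image as a :class:`Series4D`.

    The acquisition spec is inferred from the t-extent and, when the header
    carries a positive 4th pixdim with known time units, the frame duration;
    otherwise the default 60 ms applies.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise DimensionalityError(
            f"{path}: expected a 4D image, got {data.ndim}D"
        )
    zooms = img.header.get_zooms()
    frame_ms = 60.0
    if len(zooms) >= 4 and zooms[3] > 0:
        _, t_unit = img.header.get_xyzt_units()
        frame_ms = float(zooms[3]) * _TIME_UNIT_TO_MS.get(t_unit, 1.0)
    spec = AcquisitionSpec(n_frames=data.shape[3], frame_duration_ms=frame_ms)
    voxel = tuple(float(z) for z in zooms[:3]) if len(zooms) >= 3 else (1.0, 1.0, 1.0)
    return Series4D(data=np.asarray(data, dtype=float), spec=spec,
                    voxel_size_mm=voxel)


def write_series4d(series: Series4D, path) -> None:
    """Write a :class:`Series4D` to NIfTI-1 (float64, lossless round-trip)."""
    affine = np.diag(list(series.voxel_size_mm) + [1.0])
    img = nib.Nifti1Image(series.data.astype(np.float64), affine)
    img.header.set_zooms(tuple(series.voxel_size_mm)
                         + (series.spec.frame_duration_ms,))
    img.header.set_xyzt_units(xyz="mm", t="msec")
    nib.save(img, str(path))


def write_volume(volume: np.ndarray, path, voxel_size_mm=(1.0, 1.0, 1.0)) -> None:
    """Write a 3D volume (e.g. mask or TTP map) to NIfTI-1."""
    affine = np.diag(list(voxel_size_mm) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(volume, dtype=np.float64), affine),
             str(path))


# --------------------------------------------------------------------------
# cohort CSV I/O
# --------------------------------------------------------------------------

_NA_STRINGS = {"", "n/a", "na", "nan", "none"}


def _parse_cell(raw, kind, row_label, col):
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return None
    s = str(raw).strip()
    if s.lower() in _NA_STRINGS:
        return None
    try:
        if kind is bool:
            if s.lower() in ("true", "1", "yes", "y"):
                return True
            if s.lower() in ("false", "0", "no", "n"):
                return False
            raise ValueError(s)
        if kind is int:
            return int(round(float(s)))
        if kind is float:
            return float(s)
        return s
    except ValueError as exc:
        raise ValidationError(
            f"row {row_label}: cannot parse {col}={raw!r} as {kind.__name__}"
        ) from exc


_COLUMN_KINDS = {
    "patient_id": str, "sex": str, "age_years": float,
    "days_symptom_to_mri": int, "mri_signal_code": int, "etco2_mmHg": float,
    "swi_score": int, "ttp_frames": float, "hemoglobin_g_dl": float,
    "hematocrit_pct": float, "creatinine": float, "urea": float,
    "anesthesia": bool, "exclusion_reason": str,
}


def read_cohort_csv(path, schema: Optional[dict] = None) -> CohortTable:
    """Parse a cohort CSV into a validated :class:`CohortTable`.

    Parameters
    ----------
    path : path-like
        CSV with a header row; missing values as ``n/a`` or empty cells.
    schema : dict, optional
        Mapping from file column names to canonical field names
        (e.g. ``{"Hb [g/dL]": "hemoglobin_g_dl"}``). Unmapped canonical
        names are taken verbatim from the header.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if schema:
        df = df.rename(columns=schema)
    records = []
    for idx, row in df.iterrows():
        label = row.get("patient_id") or f"#{idx + 2}"  # +2: header + 1-based
        kwargs = {}
        for col in df.columns:
            if col not in _COLUMN_KINDS:
                continue
            kwargs[col] = _parse_cell(row[col], _COLUMN_KINDS[col], label, col)
        if kwargs.get("anesthesia") is None:
            kwargs["anesthesia"] = False
        try:
            records.append(PatientRecord(**kwargs))
        except ValidationError as exc:
            raise ValidationError(f"row {label}: {exc}") from exc
        except TypeError as exc:
            raise ValidationError(f"row {label}: missing required column ({exc})")
    return CohortTable(records)


def write_cohort_csv(table: CohortTable, path) -> None:
    """Write a cohort table as CSV with ``n/a`` for missing values."""
    df = table.to_dataframe()
    df["anesthesia"] = df["anesthesia"].map({True: "true", False: "false"})
    df.to_csv(path, index=False, na_rep="n/a")


# --------------------------------------------------------------------------
# bundled cohort fixture
# --------------------------------------------------------------------------

def _fixture_path(name: str) -> Path:
    return Path(resources.files("cereflow").joinpath("data", name))


def load_hus_cohort() -> CohortTable:
    """The 36 HUS patients included in the published cohort analysis.

    Transcribed verbatim from the study's demographics table: SWI venous
    contrast score (1-4), global TTP in frames, conventional-MRI signal-change
    code, end-tidal CO2 where recorded, and the anesthesia flag. Clinical
    chemistry lives in the supplementary table and is merged separately when
    available (:meth:`CohortTable.with_clinical`).
    """
    return read_cohort_csv(_fixture_path("hus_cohort_included.csv"))


def load_hus_cohort_excluded() -> CohortTable:
    """Patients scanned but excluded from the final analysis (never enters
    any statistic)."""
    return read_cohort_csv(_fixture_path("hus_cohort_excluded.csv"))
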