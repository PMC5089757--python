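"""Synthetic 4D inflow phantoms and cohort tables with known ground truth.

No imaging data accompanies the cohort analysis this package re-implements,
so every pipeline stage is exercised on phantoms built here:

* :func:`generate_phantom` places a tube (or Y-branch) of gamma-variate
  inflow curves — the standard model of a spin-labeled bolus,
  ``A * ((t - t0)/tau)**alpha * exp(-(t - t0)/tau)`` with analytic mode
  ``t0 + alpha * tau`` — in a 3D grid, with a spatially varying arrival
  time along the vessel and additive noise, and returns the exact
  per-voxel and global TTP alongside the series.
* :func:`generate_cohort` draws patient tables with a controllable
  anemia-TTP-venous-contrast correlation structure (hemoglobin drives
  hematocrit and TTP through linear links; an ordinal score is obtained by
  thresholding a latent contrast variable), returning the generating
  parameters for recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage
from scipy.stats import norm

from .core import (
    AcquisitionSpec,
    CohortTable,
    PatientRecord,
    Series4D,
    TTPMap,
    VesselMask,
)
from .errors import ValidationError

__all__ = [
    "PhantomSpec",
    "PhantomResult",
    "generate_phantom",
    "CohortSpec",
    "CohortResult",
    "generate_cohort",
    "gamma_variate",
    "link_for_correlation",
]


def gamma_variate(t, amplitude: float, onset: float, shape: float,
                  scale: float) -> np.ndarray:
    """Gamma-variate inflow curve; zero before onset, mode at
    ``onset + shape * scale``."""
    t = np.asarray(t, dtype=float)
    dt = t - onset
    out = np.zeros_like(dt)
    pos = dt > 0
    x = dt[pos] / scale
    out[pos] = amplitude * x ** shape * np.exp(-x)
    return out


# --------------------------------------------------------------------------
# 4D inflow phantom
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, inflow-curve and noise parameters of a 4D phantom.

    The vessel runs along the x axis; the arrival-time field is affine in
    the position along the vessel, from ``arrival_start_frames`` at entry to
    ``arrival_end_frames`` at exit. ``noise_sigma`` is the Gaussian noise SD
    as a fraction of the curve amplitude (0.05 = SNR 20); background voxels
    carry ``background_level``. Noise is clipped at zero intensity.
    """

    grid_shape: tuple[int, int, int] = (32, 32, 32)
    vessel_geometry: str = "straight_tube"  # or "Y_branch"
    vessel_radius_voxels: float = 1.5
    arrival_start_frames: float = 0.0
    arrival_end_frames: float = 3.0
    curve_amplitude: float = 100.0
    curve_onset_frames: float = 2.0
    curve_shape: float = 3.0
    curve_scale_frames: float = 1.0
    background_level: float = 1.0
    noise_sigma: float = 0.05
    noise_model: str = "gaussian"  # or "rician"
    seed: int = 0
    acquisition: AcquisitionSpec = field(default_factory=AcquisitionSpec)

    def __post_init__(self):
        if any(s < 4 for s in self.grid_shape):
            raise ValidationError("grid_shape must be at least 4 per axis")
        if self.vessel_geometry not in ("straight_tube", "Y_branch"):
            raise ValidationError(
                f"unknown vessel_geometry {self.vessel_geometry!r}")
        if self.vessel_radius_voxels <= 0:
            raise ValidationError("vessel_radius_voxels must be positive")
        if self.curve_amplitude <= 0 or self.curve_scale_frames <= 0:
            raise ValidationError("curve amplitude and scale must be positive")
        if self.curve_shape <= 0:
            raise ValidationError("curve_shape must be positive")
        if self.background_level < 0 or self.noise_sigma < 0:
            raise ValidationError("background and noise must be nonnegative")
        if self.noise_model not in ("gaussian", "rician"):
            raise ValidationError(f"unknown noise_model {self.noise_model!r}")
        n = self.acquisition.n_frames
        mode = self.curve_shape * self.curve_scale_frames
        for delta in (self.arrival_start_frames, self.arrival_end_frames):
            ttp = self.curve_onset_frames + delta + mode
            if not (1.0 <= ttp <= n):
                raise ValidationError(
                    f"arrival-time field puts a voxel TTP at {ttp:.2f} frames, "
                    f"outside [1, {n}]")

    @property
    def mode_frames(self) -> float:
        """Analytic mode offset of the inflow curve (alpha * tau)."""
        return self.curve_shape * self.curve_scale_frames


@dataclass
class PhantomResult:
    series: Series4D
    vessel_mask: VesselMask
    ttp_truth: TTPMap
    global_ttp_truth: float


def _centerline(spec: PhantomSpec) -> np.ndarray:
    """Boolean centerline volume of the requested geometry."""
    nx, ny, nz = spec.grid_shape
    cy, cz = ny // 2, nz // 2
    line = np.zeros(spec.grid_shape, dtype=bool)
    if spec.vessel_geometry == "straight_tube":
        line[:, cy, cz] = True
        return line
    # Y branch: trunk along x, then two 45-degree branches in the y plane
    split = nx // 2
    line[:split, cy, cz] = True
    for x in range(split, nx):
        off = x - split
        for sign in (-1, 1):
            yy = cy + sign * off
            if 0 <= yy < ny:
                line[x, yy, cz] = True
    return line


def generate_phantom(spec: PhantomSpec = PhantomSpec()) -> PhantomResult:
    """Build a 4D inflow series with exact TTP ground truth.

    Vessel voxels (within ``vessel_radius_voxels`` of the centerline) carry
    the gamma-variate curve delayed by the local arrival time; background
    voxels carry the constant background level; noise is added everywhere
    and intensities are clipped at 0. Ground truth: the vessel mask, the
    per-voxel TTP map (``onset + delta(x) + alpha*tau``), and the global TTP
    (its mean over vessel voxels).
    """
    nx = spec.grid_shape[0]
    n_frames = spec.acquisition.n_frames
    frames = np.arange(1, n_frames + 1, dtype=float)

    line = _centerline(spec)
    dist = ndimage.distance_transform_edt(~line)
    vessel = dist <= spec.vessel_radius_voxels

    # arrival time: affine in the position along the vessel (x coordinate)
    xpos = np.arange(nx, dtype=float) / max(nx - 1, 1)
    delta_x = (spec.arrival_start_frames
               + (spec.arrival_end_frames - spec.arrival_start_frames) * xpos)
    delta = np.broadcast_to(delta_x[:, None, None], spec.grid_shape)

    data = np.full(spec.grid_shape + (n_frames,), spec.background_level,
                   dtype=float)
    vx = np.argwhere(vessel)
    d_vessel = delta[vessel]
    # one curve per distinct arrival time (delta depends on x only)
    for d in np.unique(d_vessel):
        curve = gamma_variate(frames, spec.curve_amplitude,
                              spec.curve_onset_frames + d,
                              spec.curve_shape, spec.curve_scale_frames)
        sel = vx[d_vessel == d]
        data[sel[:, 0], sel[:, 1], sel[:, 2], :] = curve

    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        sd = spec.noise_sigma * spec.curve_amplitude
        if spec.noise_model == "gaussian":
            data = data + rng.normal(0.0, sd, size=data.shape)
        else:  # rician: magnitude of a complex signal with Gaussian noise
            re = data + rng.normal(0.0, sd, size=data.shape)
            im = rng.normal(0.0, sd, size=data.shape)
            data = np.hypot(re, im)
    data = np.clip(data, 0.0, None)

    series = Series4D(data=data, spec=spec.acquisition)
    mask = VesselMask(vessel)
    ttp_values = np.full(spec.grid_shape, np.nan)
    ttp_values[vessel] = (spec.curve_onset_frames + d_vessel
                          + spec.mode_frames)
    ttp_truth = TTPMap(values=ttp_values, mask=mask)
    return PhantomResult(
        series=series, vessel_mask=mask, ttp_truth=ttp_truth,
        global_ttp_truth=float(ttp_values[vessel].mean()),
    )


# --------------------------------------------------------------------------
# synthetic cohort
# --------------------------------------------------------------------------

def link_for_correlation(rho: float, x_sd: float, y_sd: float
                         ) -> tuple[float, float]:
    """Slope and residual SD of a linear link ``y = slope*x + eps`` giving
    Pearson correlation ``rho`` and marginal SD ``y_sd``."""
    if not (-1.0 < rho < 1.0):
        raise ValidationError("rho must be in (-1, 1)")
    slope = rho * y_sd / x_sd
    noise_sd = y_sd * math.sqrt(1.0 - rho * rho)
    return slope, noise_sd


@dataclass(frozen=True)
class CohortSpec:
    """Generating model of a synthetic patient cohort.

    Hemoglobin is the driver: ``hb ~ N(hb_mean, hb_sd)`` (defaults match the
    anemic cohort: 8.2 +- 1.4 g/dL), hematocrit and TTP follow linear links
    with Gaussian residuals, and the ordinal venous-contrast score 1-4 comes
    from thresholding a latent contrast variable (linear in standardized Hb
    and TTP plus noise) at three strictly increasing cutpoints. Default
    cutpoints reproduce the observed score marginal (19/10/4/3 of 36).
    """

    n_patients: int = 36
    hb_mean: float = 8.2
    hb_sd: float = 1.4
    hct_slope: float = 2.89   # %/ (g/dL); 2.89 * 8.2 ~= the cohort mean 23.7
    hct_noise_sd: float = 1.5
    ttp_intercept: float = 5.03  # frames; 5.03 + 0.35 * 8.2 ~= 7.9
    ttp_slope: float = 0.35   # frames per g/dL
    ttp_noise_sd: float = 1.31
    latent_hb_weight: float = 0.5
    latent_ttp_weight: float = 0.25
    latent_noise_sd: float = 0.775
    swi_latent_thresholds: tuple[float, float, float] = (
        # standard-normal quantiles of cumulative 19/36, 29/36, 33/36
        0.0702, 0.8632, 1.3830,
    )
    etco2_mean: float = 30.9
    etco2_sd: float = 5.5
    anesthesia_fraction: float = 15 / 36
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 1:
            raise ValidationError("n_patients must be positive")
        if self.hb_sd <= 0:
            raise ValidationError("hb_sd must be positive")
        t = self.swi_latent_thresholds
        if not (t[0] < t[1] < t[2]):
            raise ValidationError("cutpoints must be strictly increasing")

    def implied_correlations(self) -> dict:
        """Population Pearson correlations implied by the linear links."""
        ttp_sd = math.hypot(self.ttp_slope * self.hb_sd, self.ttp_noise_sd)
        hct_sd = math.hypot(self.hct_slope * self.hb_sd, self.hct_noise_sd)
        return {
            "hb_ttp": (self.ttp_slope * self.hb_sd / ttp_sd) if ttp_sd else 0.0,
            "hb_hct": (self.hct_slope * self.hb_sd / hct_sd) if hct_sd else 0.0,
            "ttp_sd": ttp_sd,
            "hct_sd": hct_sd,
        }


@dataclass
class CohortResult:
    table: CohortTable
    truth: dict


def generate_cohort(spec: CohortSpec = CohortSpec()) -> CohortResult:
    """Draw a synthetic cohort table; ``truth`` carries the generating
    parameters and implied correlations for recovery tests."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients

    hb = rng.normal(spec.hb_mean, spec.hb_sd, size=n)
    hct = spec.hct_slope * hb + rng.normal(0.0, spec.hct_noise_sd, size=n)
    ttp = (spec.ttp_intercept + spec.ttp_slope * hb
           + rng.normal(0.0, spec.ttp_noise_sd, size=n))
    ttp = np.clip(ttp, 0.5, None)  # TTP is a positive time
    hct = np.clip(hct, 1.0, None)

    implied = spec.implied_correlations()
    z_hb = (hb - spec.hb_mean) / spec.hb_sd
    ttp_mu = spec.ttp_intercept + spec.ttp_slope * spec.hb_mean
    z_ttp = (ttp - ttp_mu) / implied["ttp_sd"] if implied["ttp_sd"] else ttp * 0
    latent = (spec.latent_hb_weight * z_hb + spec.latent_ttp_weight * z_ttp
              + rng.normal(0.0, spec.latent_noise_sd, size=n))
    score = 1 + np.searchsorted(np.asarray(spec.swi_latent_thresholds), latent)

    sex = np.where(rng.random(n) < 23 / 36, "f", "m")
    age = np.clip(rng.normal(38.2, 19.3, size=n), 1.0, None)
    anesthesia = rng.random(n) < spec.anesthesia_fraction
    etco2 = rng.normal(spec.etco2_mean, spec.etco2_sd, size=n)
    mri_code = rng.choice([0, 1, 6, 7], size=n, p=[20 / 36, 2 / 36, 11 / 36, 3 / 36])

    records = []
    for i in range(n):
        records.append(PatientRecord(
            patient_id=str(i + 1),
            sex=str(sex[i]),
            age_years=float(age[i]),
            anesthesia=bool(anesthesia[i]),
            days_symptom_to_mri=int(rng.integers(0, 23)),
            mri_signal_code=int(mri_code[i]),
            etco2_mmHg=float(max(etco2[i], 5.0)) if anesthesia[i] else None,
            swi_score=int(score[i]),
            ttp_frames=float(ttp[i]),
            hemoglobin_g_dl=float(max(hb[i], 0.5)),
            hematocrit_pct=float(hct[i]),
        ))
    table = CohortTable(records)
    truth = {
        "hb_mean": spec.hb_mean, "hb_sd": spec.hb_sd,
        "ttp_slope": spec.ttp_slope, "hct_slope": spec.hct_slope,
        "r_hb_ttp": implied["hb_ttp"], "r_hb_hct": implied["hb_hct"],
        "cutpoints": tuple(spec.swi_latent_thresholds),
        "seed": spec.seed,
    }
    return CohortResult(table=table, truth=truth)
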