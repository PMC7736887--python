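"""Digital breast-PET phantoms and paired acquisition simulation.

The simulator emulates the measurement situation of a paired breast-PET
study: one ground-truth activity distribution (a heterogeneous lesion
inside breast parenchyma, with a liver region present only in the
whole-body field of view) is imaged twice —

* a dedicated-breast configuration: 1 mm isotropic voxels, narrow point
  spread function (PSF), field of view restricted to the breast;
* a whole-body configuration: 4 mm isotropic voxels, wide PSF, full
  field of view including the liver.

The acquisition model is deliberately an image-domain abstraction:
Gaussian PSF blur, block-averaging onto the output grid (which conserves
total activity), and additive heteroscedastic noise.  Sinogram-level
physics and iterative reconstruction are out of scope.

Ground-truth activity is expressed on an SUV-equivalent scale and
converted to activity concentration (Bq/mL) using the simulated
patient's injected dose and body weight, so that the downstream SUV
conversion round-trips exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .volume import UptakeVolume

__all__ = [
    "PatientAttributes",
    "LesionSpec",
    "ActivityPhantom",
    "AcquisitionConfig",
    "CohortCase",
    "build_phantom",
    "simulate_acquisition",
    "generate_cohort",
    "default_acquisition_configs",
]

# ---------------------------------------------------------------------------
# Phantom geometry (fine grid).  The breast is an ellipsoid occupying the
# lower part of the domain; the liver sits above it and is only seen by the
# whole-body field of view.  All lengths in mm.
# ---------------------------------------------------------------------------

FINE_SPACING_MM = 0.5
DOMAIN_SHAPE = (160, 160, 288)  # 80 x 80 x 144 mm at 0.5 mm
BREAST_CENTER_MM = (40.0, 40.0, 44.0)
BREAST_SEMIAXES_MM = (38.0, 38.0, 42.0)
LIVER_CENTER_MM = (40.0, 40.0, 118.0)
LIVER_SEMIAXES_MM = (30.0, 30.0, 20.0)
MYOCARDIUM_CENTER_MM = (40.0, 12.0, 96.0)
MYOCARDIUM_SEMIAXES_MM = (14.0, 10.0, 12.0)
DB_FOV_Z_MM = 88.0  # dedicated-breast axial field of view

LABEL_AIR, LABEL_PARENCHYMA, LABEL_LESION, LABEL_LIVER, LABEL_MYOCARDIUM = range(5)

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class PatientAttributes:
    """Per-scan patient attributes needed for SUV/SUL normalization."""

    sex: str = "F"
    body_weight_kg: float = 66.6
    height_m: float = 1.62
    injected_dose_mbq: float = 185.7
    uptake_time_min: float = 45.0
    blood_glucose_mg_dl: float = 95.0

    def __post_init__(self) -> None:
        if self.body_weight_kg <= 0:
            raise ValueError("body weight must be positive")
        if self.height_m <= 0:
            raise ValueError("height must be positive")
        if self.injected_dose_mbq <= 0:
            raise ValueError("injected dose must be positive")
        if self.uptake_time_min < 0:
            raise ValueError("uptake time must be non-negative")


@dataclass(frozen=True)
class LesionSpec:
    """Geometry and uptake of a single spherical lesion.

    ``diameter_cm`` doubles as the lesion's MRI longest diameter
    (``d_MRI``) carried through to the stratified analysis.
    """

    center_mm: tuple[float, float, float] = BREAST_CENTER_MM
    diameter_cm: float = 3.4
    base_uptake_suv: float = 8.0
    heterogeneity_amplitude: float = 0.3
    heterogeneity_length_mm: float = 8.0

    def __post_init__(self) -> None:
        if self.diameter_cm <= 0:
            raise ValueError("lesion diameter must be positive")
        if self.base_uptake_suv <= 0:
            raise ValueError("lesion base uptake must be positive")
        if not (0.0 <= self.heterogeneity_amplitude < 1.0):
            raise ValueError("heterogeneity amplitude must lie in [0, 1)")
        if self.heterogeneity_length_mm <= 0:
            raise ValueError("heterogeneity correlation length must be positive")

    @property
    def radius_mm(self) -> float:
        return self.diameter_cm * 10.0 / 2.0


@dataclass
class ActivityPhantom:
    """Ground-truth activity (SUV-equivalent scale) on the fine grid."""

    activity: np.ndarray  # float32, SUV-equivalent units
    labels: np.ndarray  # uint8 tissue labels
    spacing_mm: float
    lesion: LesionSpec
    attrs: PatientAttributes
    seed: int
    parenchyma_suv: float
    liver_suv: float

    @property
    def lesion_mask(self) -> np.ndarray:
        return self.labels == LABEL_LESION

    @property
    def lesion_volume_ml(self) -> float:
        return float(self.lesion_mask.sum()) * self.spacing_mm**3 / 1000.0


@dataclass(frozen=True)
class AcquisitionConfig:
    """Image-domain acquisition model for one modality."""

    modality: str  # "db" | "wb"
    voxel_mm: float
    psf_fwhm_mm: float
    noise_coefficient: float
    fov: str  # "single-breast" | "whole-body"

    def __post_init__(self) -> None:
        if self.modality not in ("db", "wb"):
            raise ValueError("modality must be 'db' or 'wb'")
        if self.voxel_mm <= 0:
            raise ValueError("output voxel spacing must be positive")
        if self.psf_fwhm_mm < 0:
            raise ValueError("PSF FWHM must be non-negative")
        if self.noise_coefficient < 0:
            raise ValueError("noise coefficient must be non-negative")
        if self.fov not in ("single-breast", "whole-body"):
            raise ValueError("fov must be 'single-breast' or 'whole-body'")


def default_acquisition_configs() -> dict[str, AcquisitionConfig]:
    """The paired default configurations (1 mm/narrow-PSF db, 4 mm/wide-PSF wb)."""
    return {
        "db": AcquisitionConfig("db", voxel_mm=1.0, psf_fwhm_mm=2.0,
                                noise_coefficient=0.10, fov="single-breast"),
        "wb": AcquisitionConfig("wb", voxel_mm=4.0, psf_fwhm_mm=7.0,
                                noise_coefficient=0.05, fov="whole-body"),
    }


# ---------------------------------------------------------------------------
# Phantom construction
# ---------------------------------------------------------------------------

def _ellipsoid_mask(center, semiaxes) -> np.ndarray:
    sp = FINE_SPACING_MM
    ii, jj, kk = np.ogrid[: DOMAIN_SHAPE[0], : DOMAIN_SHAPE[1], : DOMAIN_SHAPE[2]]
    x = (ii + 0.5) * sp - center[0]
    y = (jj + 0.5) * sp - center[1]
    z = (kk + 0.5) * sp - center[2]
    return (
        (x / semiaxes[0]) ** 2 + (y / semiaxes[1]) ** 2 + (z / semiaxes[2]) ** 2
    ) <= 1.0


def _sphere_mask(center, radius) -> np.ndarray:
    return _ellipsoid_mask(center, (radius, radius, radius))


def _correlated_field(shape, length_mm, rng) -> np.ndarray:
    """Zero-mean, unit-variance Gaussian random field with a given correlation length."""
    white = rng.standard_normal(shape)
    sigma_vox = max(length_mm * _FWHM_TO_SIGMA / FINE_SPACING_MM, 1e-6)
    smooth = ndimage.gaussian_filter(white, sigma=sigma_vox, mode="reflect")
    sd = smooth.std()
    if sd == 0:
        return np.zeros(shape)
    return (smooth - smooth.mean()) / sd


def build_phantom(
    lesion: LesionSpec,
    attrs: PatientAttributes | None = None,
    seed: int = 0,
    *,
    parenchyma_suv_range: tuple[float, float] = (0.3, 1.5),
    liver_suv_range: tuple[float, float] = (1.8, 2.6),
    myocardium: bool = False,
    myocardium_suv_range: tuple[float, float] = (2.0, 5.0),
) -> ActivityPhantom:
    """Build a ground-truth activity phantom around one spherical lesion.

    Deterministic for a fixed ``seed``.  Parenchyma and liver uptake are
    drawn once per phantom from the given ranges, emulating inter-patient
    variation in the normal-tissue background.  Lesion uptake is
    ``base_uptake × (1 + f)`` with ``f`` a correlated random field scaled
    to the heterogeneity amplitude and clipped to ``[-amplitude,
    amplitude]``; amplitude 0 yields an exactly uniform lesion.

    Raises
    ------
    ValueError
        If the lesion (as voxelized) extends outside the breast volume.
    """
    if attrs is None:
        attrs = PatientAttributes()
    rng = np.random.default_rng(seed)
    parenchyma = float(rng.uniform(*parenchyma_suv_range))
    liver = float(rng.uniform(*liver_suv_range))

    breast = _ellipsoid_mask(BREAST_CENTER_MM, BREAST_SEMIAXES_MM)
    lesion_vox = _sphere_mask(lesion.center_mm, lesion.radius_mm)
    if not lesion_vox.any():
        raise ValueError("lesion does not cover any voxel at the phantom resolution")
    outside = lesion_vox & ~breast
    if outside.any():
        raise ValueError(
            f"lesion at {lesion.center_mm} mm with diameter {lesion.diameter_cm} cm "
            f"extends outside the breast volume ({int(outside.sum())} voxels outside)"
        )

    labels = np.zeros(DOMAIN_SHAPE, dtype=np.uint8)
    labels[breast] = LABEL_PARENCHYMA
    labels[_ellipsoid_mask(LIVER_CENTER_MM, LIVER_SEMIAXES_MM)] = LABEL_LIVER
    if myocardium:
        labels[_ellipsoid_mask(MYOCARDIUM_CENTER_MM, MYOCARDIUM_SEMIAXES_MM)] = (
            LABEL_MYOCARDIUM
        )
    labels[lesion_vox] = LABEL_LESION

    activity = np.zeros(DOMAIN_SHAPE, dtype=np.float32)
    activity[labels == LABEL_PARENCHYMA] = parenchyma
    activity[labels == LABEL_LIVER] = liver
    if myocardium:
        activity[labels == LABEL_MYOCARDIUM] = float(rng.uniform(*myocardium_suv_range))

    if lesion.heterogeneity_amplitude == 0:
        activity[lesion_vox] = lesion.base_uptake_suv
    else:
        # Correlated field on the lesion bounding box only (cheap, deterministic).
        bbox = ndimage.find_objects(lesion_vox.astype(np.uint8))[0]
        sub = lesion_vox[bbox]
        f = _correlated_field(sub.shape, lesion.heterogeneity_length_mm, rng)
        f = np.clip(
            f * lesion.heterogeneity_amplitude,
            -lesion.heterogeneity_amplitude,
            lesion.heterogeneity_amplitude,
        )
        les = np.asarray(lesion.base_uptake_suv * (1.0 + f), dtype=np.float32)
        block = activity[bbox]
        block[sub] = les[sub]

    if not activity[lesion_vox].mean() > parenchyma:
        raise ValueError("lesion mean activity must exceed the parenchyma background")

    return ActivityPhantom(
        activity=activity,
        labels=labels,
        spacing_mm=FINE_SPACING_MM,
        lesion=lesion,
        attrs=attrs,
        seed=int(seed),
        parenchyma_suv=parenchyma,
        liver_suv=liver,
    )


# ---------------------------------------------------------------------------
# Acquisition simulation
# ---------------------------------------------------------------------------

def _block_average(arr: np.ndarray, factor: int) -> np.ndarray:
    n0, n1, n2 = arr.shape
    if any(n % factor for n in arr.shape):
        raise ValueError(
            f"grid shape {arr.shape} not divisible by downsampling factor {factor}"
        )
    view = arr.reshape(n0 // factor, factor, n1 // factor, factor, n2 // factor, factor)
    return view.mean(axis=(1, 3, 5), dtype=np.float64)


def simulate_acquisition(
    phantom: ActivityPhantom,
    config: AcquisitionConfig,
    seed: int = 0,
    attrs: PatientAttributes | None = None,
) -> UptakeVolume:
    """Image the phantom under one acquisition configuration.

    Pipeline: field-of-view crop → isotropic Gaussian PSF blur →
    block-average onto the output grid → additive Gaussian noise with
    standard deviation ``noise_coefficient × sqrt(signal)`` (on the
    SUV-equivalent scale, clipped at zero) → scale to Bq/mL using the
    patient's injected dose and body weight.

    With zero FWHM and zero noise the output is the exact block average
    of the ground truth, which conserves total activity in the field of
    view.
    """
    if attrs is None:
        attrs = phantom.attrs
    ratio = config.voxel_mm / phantom.spacing_mm
    factor = int(round(ratio))
    if factor < 1 or abs(ratio - factor) > 1e-9:
        raise ValueError(
            f"output spacing {config.voxel_mm} mm must be an integer multiple of "
            f"the phantom spacing {phantom.spacing_mm} mm"
        )

    act = np.asarray(phantom.activity, dtype=np.float64)
    lesion_mask = phantom.lesion_mask
    if config.fov == "single-breast":
        nz = int(round(DB_FOV_Z_MM / phantom.spacing_mm))
        if not lesion_mask[:, :, :nz].any():
            raise ValueError(
                f"field of view excludes lesion at {phantom.lesion.center_mm} mm"
            )
        act = act[:, :, :nz]
    elif not lesion_mask.any():
        raise ValueError("phantom contains no lesion voxels")

    if config.psf_fwhm_mm > 0:
        sigma_vox = config.psf_fwhm_mm * _FWHM_TO_SIGMA / phantom.spacing_mm
        act = ndimage.gaussian_filter(act, sigma=sigma_vox, mode="constant")

    out = _block_average(act, factor)

    if config.noise_coefficient > 0:
        rng = np.random.default_rng(seed)
        sd = config.noise_coefficient * np.sqrt(np.clip(out, 0.0, None))
        out = np.clip(out + rng.standard_normal(out.shape) * sd, 0.0, None)

    # SUV-equivalent -> Bq/mL using dose/weight (decay interval 0 by convention:
    # simulated images are already decay-corrected to the reference time).
    scale = attrs.injected_dose_mbq * 1e6 / (attrs.body_weight_kg * 1e3)
    return UptakeVolume(
        data=out * scale,
        spacing=(config.voxel_mm,) * 3,
        origin=(0.0, 0.0, 0.0),
        unit="Bq/mL",
        modality=config.modality,
    )


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

@dataclass
class CohortCase:
    """One simulated patient: a shared ground truth imaged on both modalities."""

    case_id: str
    lesion: LesionSpec
    d_mri_cm: float
    true_lesion_volume_ml: float
    parenchyma_suv: float
    liver_suv: float
    attrs_db: PatientAttributes
    attrs_wb: PatientAttributes
    db: UptakeVolume
    wb: UptakeVolume

    def image(self, modality: str) -> UptakeVolume:
        return self.db if modality == "db" else self.wb

    def attrs(self, modality: str) -> PatientAttributes:
        return self.attrs_db if modality == "db" else self.attrs_wb


def _sample_attributes(rng: np.random.Generator) -> tuple[PatientAttributes, PatientAttributes]:
    """Shared body habitus, modality-specific dose and uptake time."""
    weight = float(np.clip(rng.normal(66.0, 4.0), 45.0, 95.0))
    height = float(np.clip(rng.normal(1.62, 0.06), 1.45, 1.85))
    glucose = float(rng.uniform(75.0, 110.0))
    common = dict(sex="F", body_weight_kg=weight, height_m=height,
                  blood_glucose_mg_dl=glucose)
    attrs_db = PatientAttributes(
        injected_dose_mbq=float(rng.uniform(121.0, 199.8)),
        uptake_time_min=45.0, **common,
    )
    attrs_wb = PatientAttributes(
        injected_dose_mbq=float(rng.uniform(229.4, 392.6)),
        uptake_time_min=float(rng.uniform(50.0, 60.0)), **common,
    )
    return attrs_db, attrs_wb


def generate_cohort(
    n: int,
    seed: int = 0,
    *,
    db_config: AcquisitionConfig | None = None,
    wb_config: AcquisitionConfig | None = None,
    diameter_range_cm: tuple[float, float] = (2.0, 5.6),
    small_fraction: float = 0.4,
    base_uptake_range_suv: tuple[float, float] = (4.0, 15.0),
    heterogeneity_amplitude_range: tuple[float, float] = (0.15, 0.4),
    heterogeneity_length_range_mm: tuple[float, float] = (4.0, 10.0),
    parenchyma_suv_range: tuple[float, float] = (0.3, 1.5),
    liver_suv_range: tuple[float, float] = (1.8, 2.6),
) -> list[CohortCase]:
    """Generate ``n`` paired cases from a single master seed.

    Lesion diameters are drawn from a two-component mixture emulating
    the study design (tumors of at least 2 cm, with roughly 40% of
    lesions at or below the 2.5 cm stratification cutoff):
    with probability ``small_fraction`` uniform on the sub-cutoff part
    of ``diameter_range_cm``, otherwise uniform on the supra-cutoff
    part.  Per-case seeds are spawned deterministically from the master
    seed, so a fixed seed reproduces the cohort bit for bit.
    """
    if n < 1:
        raise ValueError("cohort size must be at least 1")
    lo, hi = diameter_range_cm
    if not (0 < lo <= hi):
        raise ValueError(f"invalid diameter range {diameter_range_cm}")
    configs = default_acquisition_configs()
    db_config = db_config or configs["db"]
    wb_config = wb_config or configs["wb"]

    cases: list[CohortCase] = []
    master = np.random.SeedSequence(seed)
    for i, child in enumerate(master.spawn(n)):
        rng = np.random.default_rng(child)
        s_phantom, s_db, s_wb = (int(x) for x in rng.integers(0, 2**31, size=3))

        cut = 2.5
        if lo < cut < hi and rng.random() < small_fraction:
            d = float(rng.uniform(lo, cut))
        elif hi <= cut:
            d = float(rng.uniform(lo, hi))
        else:
            d = float(rng.uniform(max(lo, cut), hi))

        lesion = LesionSpec(
            center_mm=BREAST_CENTER_MM,
            diameter_cm=d,
            base_uptake_suv=float(rng.uniform(*base_uptake_range_suv)),
            heterogeneity_amplitude=float(rng.uniform(*heterogeneity_amplitude_range)),
            heterogeneity_length_mm=float(rng.uniform(*heterogeneity_length_range_mm)),
        )
        attrs_db, attrs_wb = _sample_attributes(rng)
        phantom = build_phantom(
            lesion, attrs_db, seed=s_phantom,
            parenchyma_suv_range=parenchyma_suv_range,
            liver_suv_range=liver_suv_range,
        )
        db_img = simulate_acquisition(phantom, db_config, seed=s_db, attrs=attrs_db)
        wb_img = simulate_acquisition(phantom, wb_config, seed=s_wb, attrs=attrs_wb)
        cases.append(
            CohortCase(
                case_id=f"case-{i:02d}",
                lesion=lesion,
                d_mri_cm=d,
                true_lesion_volume_ml=phantom.lesion_volume_ml,
                parenchyma_suv=phantom.parenchyma_suv,
                liver_suv=phantom.liver_suv,
                attrs_db=attrs_db,
                attrs_wb=attrs_wb,
                db=db_img,
                wb=wb_img,
            )
        )
        del phantom
    return cases
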