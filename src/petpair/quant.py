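"""SUV/SUL conversion, tumor segmentation and PERCIST-style uptake metrics.

Quantification follows the conventions of the PET Response Criteria in
Solid Tumors (PERCIST): lean-body-mass-normalized uptake (SUL), a peak
uptake defined as the maximum 1.2-cm spherical-kernel mean over the
tumor, metabolic tumor volume (MTV) as the tumor sub-volume above 40% of
the VOI mean SUV, and total lesion glycolysis (TLG) as MTV times mean
uptake.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .phantom import PatientAttributes
from .volume import UptakeVolume, VoiMask

__all__ = [
    "DecayParams",
    "UptakeMetrics",
    "F18_HALF_LIFE_MIN",
    "SEGMENTATION_THRESHOLDS",
    "lean_body_mass_kg",
    "compute_suv",
    "suv_to_sul",
    "segment_tumor",
    "background_voi",
    "sul_peak",
    "metabolic_volume",
    "uptake_metrics",
]

F18_HALF_LIFE_MIN = 109.77

#: Modality-specific SUV thresholds for tumor boundary definition; the higher
#: dedicated-breast threshold suppresses its higher background noise.
SEGMENTATION_THRESHOLDS = {"db": 3.0, "wb": 2.5}

_CONNECTIVITY_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class DecayParams:
    """Radioactive decay correction parameters.

    ``interval_min`` is the time between the dose calibration reference
    and the scan; uptake measured at the scan is corrected back by
    ``2**(interval/half_life)``.
    """

    half_life_min: float = F18_HALF_LIFE_MIN
    interval_min: float = 0.0

    def __post_init__(self) -> None:
        if self.half_life_min <= 0:
            raise ValueError("half-life must be positive")

    @property
    def correction_factor(self) -> float:
        return float(2.0 ** (self.interval_min / self.half_life_min))


@dataclass
class UptakeMetrics:
    """PERCIST uptake and metabolic-volume metrics for one lesion/modality."""

    sul_max: float
    sul_mean: float
    sul_peak: float
    mtv_ml: float
    tlg: float
    tbr_contralateral: float | None
    tbr_liver: float | None
    d_mri_cm: float
    modality: str

    def __post_init__(self) -> None:
        tol = 1e-9 * max(abs(self.sul_max), 1.0)
        if self.sul_mean > self.sul_max + tol:
            raise ValueError("SUL_mean cannot exceed SUL_max")
        if self.sul_peak > self.sul_max + tol:
            raise ValueError("SUL_peak cannot exceed SUL_max")
        if self.mtv_ml < 0 or self.tlg < 0:
            raise ValueError("MTV and TLG must be non-negative")

    def to_row(self) -> dict:
        return {
            "modality": self.modality,
            "SUL_max": self.sul_max,
            "SUL_mean": self.sul_mean,
            "SUL_peak": self.sul_peak,
            "MTV_mL": self.mtv_ml,
            "TLG": self.tlg,
            "TBR_liver": self.tbr_liver,
            "TBR_contralateral": self.tbr_contralateral,
            "d_MRI_cm": self.d_mri_cm,
        }


# ---------------------------------------------------------------------------
# Unit conversion
# ---------------------------------------------------------------------------

def compute_suv(
    image: UptakeVolume, attrs: PatientAttributes, decay: DecayParams | None = None
) -> UptakeVolume:
    """Convert activity concentration (Bq/mL) to decay-corrected SUV.

    SUV = C_corrected / (injected dose [Bq] / body weight [g]); with dose
    in Bq and weight in g the result carries g/mL, numerically treated as
    dimensionless.
    """
    if image.unit != "Bq/mL":
        raise ValueError(f"expected an activity-concentration image, got {image.unit}")
    if decay is None:
        decay = DecayParams()
    dose_bq = attrs.injected_dose_mbq * 1e6
    weight_g = attrs.body_weight_kg * 1e3
    suv = np.asarray(image.data, dtype=np.float64) * decay.correction_factor / (
        dose_bq / weight_g
    )
    return image.with_data(suv, unit="SUV")


def lean_body_mass_kg(attrs: PatientAttributes, formula: str = "janmahasatian") -> float:
    """Lean body mass (kg).

    Default is the Janmahasatian estimate (the PERCIST-recommended
    formula); ``"james"`` and ``"identity"`` (LBM = weight) are also
    available.
    """
    w = attrs.body_weight_kg
    h = attrs.height_m
    if formula == "identity":
        return w
    if formula == "janmahasatian":
        bmi = w / h**2
        if attrs.sex.upper().startswith("F"):
            return 9270.0 * w / (8780.0 + 244.0 * bmi)
        return 9270.0 * w / (6680.0 + 216.0 * bmi)
    if formula == "james":
        if attrs.sex.upper().startswith("F"):
            return 1.07 * w - 148.0 * (w / (h * 100.0)) ** 2
        return 1.10 * w - 128.0 * (w / (h * 100.0)) ** 2
    raise ValueError(f"unknown lean-body-mass formula {formula!r}")


def suv_to_sul(
    image: UptakeVolume, attrs: PatientAttributes, formula: str = "janmahasatian"
) -> UptakeVolume:
    """Renormalize SUV by lean body mass: SUL = SUV × LBM / weight."""
    if image.unit != "SUV":
        raise ValueError(f"expected an SUV image, got {image.unit}")
    lbm = lean_body_mass_kg(attrs, formula)
    if lbm <= 0:
        raise ValueError(f"non-positive lean body mass ({lbm:.2f} kg) from {formula}")
    sul = np.asarray(image.data, dtype=np.float64) * (lbm / attrs.body_weight_kg)
    return image.with_data(sul, unit="SUL")


# ---------------------------------------------------------------------------
# Segmentation and geometric VOIs
# ---------------------------------------------------------------------------

def segment_tumor(
    image: UptakeVolume,
    modality: str | None = None,
    seed_point: tuple[int, int, int] | None = None,
    threshold: float | None = None,
) -> VoiMask:
    """Seeded threshold segmentation of the tumor VOI.

    The mask is the 26-connected component of ``{SUV >= threshold}``
    containing ``seed_point`` (the seed replaces the operator's click in
    the study's semi-automated workflow).  Default thresholds are 3.0
    for dedicated-breast and 2.5 for whole-body images.
    """
    if image.unit != "SUV":
        raise ValueError(f"tumor segmentation expects an SUV image, got {image.unit}")
    if modality is None:
        modality = image.modality
    if threshold is None:
        if modality not in SEGMENTATION_THRESHOLDS:
            raise ValueError(f"unknown modality {modality!r} and no threshold given")
        threshold = SEGMENTATION_THRESHOLDS[modality]
    if seed_point is None:
        raise ValueError("a seed point inside the lesion is required")
    seed_point = tuple(int(i) for i in seed_point)

    supra = np.asarray(image.data) >= threshold
    if not supra.any():
        raise ValueError(f"no voxel reaches the SUV >= {threshold} threshold")
    if not supra[seed_point]:
        raise ValueError(
            f"seed voxel {seed_point} has SUV "
            f"{float(image.data[seed_point]):.3f} < threshold {threshold}"
        )
    labeled, _ = ndimage.label(supra, structure=_CONNECTIVITY_26)
    mask = labeled == labeled[seed_point]
    return VoiMask(
        data=mask, spacing=image.spacing, origin=image.origin, role="tumor",
        meta={"threshold": float(threshold), "seed_point": seed_point},
    )


def background_voi(
    image: UptakeVolume,
    role: str,
    center: tuple[int, int, int],
    diameter_cm: float = 1.2,
    shape: str | None = None,
) -> VoiMask:
    """Geometric background VOI: 1.2 cm sphere (wb) or cylinder (db).

    The cylinder (contralateral breast on dedicated-breast images) has
    height equal to its diameter with its axis along the image's third
    axis.  Membership is by voxel-center inclusion.  A VOI clipped by
    the image boundary triggers a warning reporting the clipped
    fraction.
    """
    center = tuple(int(i) for i in center)
    if any(c < 0 or c >= n for c, n in zip(center, image.shape)):
        raise ValueError(f"VOI center {center} lies outside the image grid")
    if shape is None:
        shape = "cylinder" if image.modality == "db" else "sphere"
    if shape not in ("sphere", "cylinder"):
        raise ValueError(f"unknown VOI shape {shape!r}")

    radius_mm = diameter_cm * 10.0 / 2.0
    sp = image.spacing
    # Offsets in voxels; distance measured between voxel centers in mm.
    half = [int(np.floor(radius_mm / s)) for s in sp]
    oi, oj, ok = np.ogrid[
        -half[0] : half[0] + 1, -half[1] : half[1] + 1, -half[2] : half[2] + 1
    ]
    di, dj, dk = oi * sp[0], oj * sp[1], ok * sp[2]
    if shape == "sphere":
        inside = di**2 + dj**2 + dk**2 <= radius_mm**2
    else:
        inside = (di**2 + dj**2 <= radius_mm**2) & (np.abs(dk) <= radius_mm)

    full = int(inside.sum())
    mask = np.zeros(image.shape, dtype=bool)
    offs = np.argwhere(inside) - np.array(half)
    pts = offs + np.array(center)
    ok_pts = np.all((pts >= 0) & (pts < np.array(image.shape)), axis=1)
    kept = pts[ok_pts]
    mask[kept[:, 0], kept[:, 1], kept[:, 2]] = True
    if len(kept) < full:
        warnings.warn(
            f"background VOI clipped by the image boundary: "
            f"{1 - len(kept) / full:.1%} of {full} voxels lost",
            stacklevel=2,
        )
    return VoiMask(
        data=mask, spacing=image.spacing, origin=image.origin, role=role,
        meta={"shape": shape, "diameter_cm": diameter_cm,
              "clipped_fraction": 1 - len(kept) / full},
    )


# ---------------------------------------------------------------------------
# Uptake metrics
# ---------------------------------------------------------------------------

def sul_peak(image: UptakeVolume, tumor: VoiMask, kernel_diameter_cm: float = 1.2) -> float:
    """Peak uptake: max over tumor voxels of the spherical-kernel mean.

    For each tumor voxel, the image is averaged over all *image* voxels
    whose centers lie within the kernel radius (0.6 cm by default) of
    that voxel's center — the kernel may extend beyond the tumor mask;
    voxels beyond the image boundary are simply absent from the mean.
    """
    tumor.require_congruent(image)
    idx = np.argwhere(tumor.data)
    if idx.size == 0:
        raise ValueError("tumor mask is empty")

    radius_mm = kernel_diameter_cm * 10.0 / 2.0
    sp = image.spacing
    half = [int(np.floor(radius_mm / s)) for s in sp]
    oi, oj, ok = np.ogrid[
        -half[0] : half[0] + 1, -half[1] : half[1] + 1, -half[2] : half[2] + 1
    ]
    inside = (oi * sp[0]) ** 2 + (oj * sp[1]) ** 2 + (ok * sp[2]) ** 2 <= radius_mm**2
    offsets = np.argwhere(inside) - np.array(half)

    data = np.asarray(image.data, dtype=np.float64)
    shape = np.array(image.shape)
    sums = np.zeros(len(idx))
    counts = np.zeros(len(idx))
    for off in offsets:
        pts = idx + off
        valid = np.all((pts >= 0) & (pts < shape), axis=1)
        v = pts[valid]
        sums[valid] += data[v[:, 0], v[:, 1], v[:, 2]]
        counts[valid] += 1
    return float(np.max(sums / counts))


def metabolic_volume(
    image: UptakeVolume,
    tumor: VoiMask,
    fraction: float = 0.40,
    tlg_mean: str = "mtv",
) -> tuple[float, float]:
    """Metabolic tumor volume (mL) and total lesion glycolysis.

    MTV sums voxel volumes over the tumor sub-region with SUV at or
    above ``fraction`` of the VOI mean.  TLG = MTV × mean SUV, where the
    mean is taken over the MTV sub-region (default, the prevailing
    convention) or over the whole VOI (``tlg_mean="voi"``).
    """
    vals = tumor.values_in(image)
    if vals.size == 0:
        raise ValueError("tumor mask is empty")
    voi_mean = float(vals.mean())
    cut = fraction * voi_mean
    sub = vals[vals >= cut]
    mtv_ml = sub.size * image.voxel_volume_mm3 / 1000.0
    if tlg_mean == "mtv":
        mean_for_tlg = float(sub.mean()) if sub.size else 0.0
    elif tlg_mean == "voi":
        mean_for_tlg = voi_mean
    else:
        raise ValueError(f"tlg_mean must be 'mtv' or 'voi', got {tlg_mean!r}")
    return mtv_ml, mtv_ml * mean_for_tlg


def _safe_tbr(peak: float, background: VoiMask, sul: UptakeVolume) -> float | None:
    bg = background.values_in(sul)
    mean = float(bg.mean()) if bg.size else 0.0
    if mean <= 0:
        warnings.warn(
            f"background VOI ({background.role}) mean {mean:.3g} <= 0; "
            "TBR flagged undefined", stacklevel=2,
        )
        return None
    return peak / mean


def uptake_metrics(
    sul: UptakeVolume,
    suv: UptakeVolume,
    tumor: VoiMask,
    backgrounds: dict[str, VoiMask],
    d_mri_cm: float = float("nan"),
    *,
    mtv_fraction: float = 0.40,
    peak_kernel_diameter_cm: float = 1.2,
    tlg_mean: str = "mtv",
) -> UptakeMetrics:
    """Assemble the full uptake-metric panel for one lesion on one modality.

    ``backgrounds`` maps ``"contralateral"`` and (whole-body only)
    ``"liver"`` to their VOIs; each tumor-background ratio is the tumor
    SUL_peak divided by the background SUL_mean.
    """
    tumor.require_congruent(sul)
    tumor.require_congruent(suv)
    tvals = tumor.values_in(sul)
    if tvals.size == 0:
        raise ValueError("tumor mask is empty")
    peak = sul_peak(sul, tumor, kernel_diameter_cm=peak_kernel_diameter_cm)
    mtv_ml, tlg = metabolic_volume(suv, tumor, fraction=mtv_fraction, tlg_mean=tlg_mean)

    tbr_contra = tbr_liver = None
    if "contralateral" in backgrounds:
        tbr_contra = _safe_tbr(peak, backgrounds["contralateral"], sul)
    if "liver" in backgrounds:
        if sul.modality == "db":
            raise ValueError("liver background is only defined for whole-body images")
        tbr_liver = _safe_tbr(peak, backgrounds["liver"], sul)

    return UptakeMetrics(
        sul_max=float(tvals.max()),
        sul_mean=float(tvals.mean()),
        sul_peak=peak,
        mtv_ml=mtv_ml,
        tlg=tlg,
        tbr_contralateral=tbr_contra,
        tbr_liver=tbr_liver,
        d_mri_cm=float(d_mri_cm),
        modality=sul.modality or "?",
    )
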