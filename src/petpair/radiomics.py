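"""Radiomic feature extraction: preprocessing plus 20 morphology,
intensity, GLCM and NGTDM features, implemented from first principles
following the Image Biomarker Standardization Initiative (IBSI)
definitions.

Preprocessing chain: trilinear resampling of image and mask to a 2 mm
isotropic grid, then fixed-bin-width (FBW) gray-level discretization
with bin width 0.5 anchored at zero, so that bin ``k`` covers the
half-open interval ``[k·w, (k+1)·w)`` and absolute SUV bins are
comparable across patients and modalities.

Texture matrices use Chebyshev distance 1: the gray-level co-occurrence
matrix (GLCM) is built per direction over the 13 unique 3D offsets,
symmetrized, normalized, and the normalized matrices averaged; the
neighborhood gray-tone difference matrix (NGTDM) uses the 26-voxel
neighborhood restricted to in-mask voxels.  All logarithms are base 2
(entropies in bits).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import QhullError, ConvexHull
from scipy.spatial.distance import pdist
from skimage import measure

from .volume import UptakeVolume, VoiMask

__all__ = [
    "FEATURE_NAMES",
    "DiscretizedVolume",
    "resample_isotropic",
    "discretize_fbw",
    "morphology_features",
    "intensity_features",
    "glcm_features",
    "ngtdm_features",
    "extract_features",
]

#: The 20 reported features, in report order.
FEATURE_NAMES = (
    "mesh_volume",
    "surface_area",
    "sphericity",
    "max_3d_diameter",
    "entropy",
    "uniformity",
    "skewness",
    "kurtosis",
    "standard_deviation",
    "glcm_contrast",
    "glcm_correlation",
    "glcm_inverse_difference",
    "glcm_normalized_inverse_difference",
    "glcm_joint_energy",
    "glcm_joint_entropy",
    "ngtdm_busyness",
    "ngtdm_coarseness",
    "ngtdm_complexity",
    "ngtdm_contrast",
    "ngtdm_strength",
)

#: Sentinel for flat-region NGTDM coarseness.
COARSENESS_CAP = 1e6

# The 13 unique direction vectors at Chebyshev distance 1 in 3D.
DIRECTIONS_13 = tuple(
    (di, dj, dk)
    for di in (-1, 0, 1)
    for dj in (-1, 0, 1)
    for dk in (-1, 0, 1)
    if (di, dj, dk) > (0, 0, 0)
)


@dataclass
class DiscretizedVolume:
    """Integer gray levels (1..n_levels) inside a mask; 0 outside."""

    levels: np.ndarray  # int array, 0 = out-of-mask sentinel
    bin_width: float
    n_levels: int
    mask: VoiMask

    def in_mask_levels(self) -> np.ndarray:
        return self.levels[self.mask.data]


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def resample_isotropic(
    image: UptakeVolume, mask: VoiMask, target_mm: float = 2.0
) -> tuple[UptakeVolume, VoiMask]:
    """Trilinearly resample image and mask onto an isotropic grid.

    The output grid shares the input origin; the grid length is chosen
    so no sample center falls beyond the last input voxel center, and
    values are clamped to the nearest edge voxel where an output center
    precedes the first input center (the usual half-voxel boundary band
    when upsampling).  The mask is interpolated as a real-valued field
    and re-binarized at 0.5.  An input already at the target spacing is
    returned unchanged.
    """
    mask.require_congruent(image)
    if target_mm <= 0:
        raise ValueError("target spacing must be positive")
    if np.allclose(image.spacing, target_mm):
        return image, mask

    sp = image.spacing
    shape = image.shape
    new_n = [
        max(1, int(np.floor(((n - 0.5) * s - 0.5 * target_mm) / target_mm)) + 1)
        for n, s in zip(shape, sp)
    ]
    # Fractional input index of each output voxel center.
    coords = np.meshgrid(
        *[((np.arange(m) + 0.5) * target_mm) / s - 0.5 for m, s in zip(new_n, sp)],
        indexing="ij",
    )
    img_new = ndimage.map_coordinates(
        np.asarray(image.data, dtype=np.float64), coords, order=1, mode="nearest"
    )
    mask_new = (
        ndimage.map_coordinates(
            mask.data.astype(np.float64), coords, order=1, mode="nearest"
        )
        >= 0.5
    )
    if not mask_new.any():
        raise ValueError(
            f"mask ({mask.role}) is empty after resampling to {target_mm} mm"
        )
    out_img = UptakeVolume(
        data=img_new, spacing=(target_mm,) * 3, origin=image.origin,
        unit=image.unit, modality=image.modality,
    )
    out_mask = VoiMask(
        data=mask_new, spacing=(target_mm,) * 3, origin=image.origin, role=mask.role
    )
    return out_img, out_mask


def discretize_fbw(
    image: UptakeVolume, mask: VoiMask, bin_width: float = 0.5
) -> DiscretizedVolume:
    """Fixed-bin-width discretization anchored at zero.

    ``level(x) = floor(x / w) + 1`` with half-open bins ``[k·w,
    (k+1)·w)``; a value exactly on an edge belongs to the upper bin.
    ``n_levels`` is the maximum in-mask level — intermediate levels with
    zero count keep their place so GLCM indices map directly to absolute
    uptake bins.
    """
    mask.require_congruent(image)
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    vals = mask.values_in(image)
    if vals.size == 0:
        raise ValueError("mask is empty")
    if np.any(vals < 0):
        raise ValueError("negative in-mask values; SUV images must be non-negative")
    levels = np.zeros(image.shape, dtype=np.int64)
    levels[mask.data] = np.floor(vals / bin_width).astype(np.int64) + 1
    return DiscretizedVolume(
        levels=levels,
        bin_width=float(bin_width),
        n_levels=int(levels.max()),
        mask=mask,
    )


# ---------------------------------------------------------------------------
# Morphology
# ---------------------------------------------------------------------------

#: Pre-mesh Gaussian smoothing (voxel units) applied to the binary mask
#: before extracting the 0.5-level surface: suppresses the staircase
#: artifact that otherwise inflates surface area (and deflates
#: sphericity) on digitized smooth shapes.
_MESH_SMOOTHING_SIGMA_VOX = 0.8


def _marching_mesh(field: np.ndarray, spacing) -> tuple[float, float]:
    verts, faces, _, _ = measure.marching_cubes(field, level=0.5, spacing=spacing)
    v0, v1, v2 = (verts[faces[:, i]] for i in range(3))
    volume = abs(float(np.einsum("ij,ij->", v0, np.cross(v1, v2))) / 6.0)
    area = float(measure.mesh_surface_area(verts, faces))
    if volume <= 0 or area <= 0:
        raise ValueError("degenerate mesh")
    return volume, area


def _mesh_volume_area(mask: VoiMask) -> tuple[float, float, bool]:
    """Mesh volume (mm^3) and surface area (mm^2) of the 0.5-level surface
    of the (lightly smoothed) binary mask; falls back to the raw binary
    surface for thin masks and to a voxel-box estimate for degenerate
    (e.g. single-voxel) masks."""
    pad = int(np.ceil(4.0 * _MESH_SMOOTHING_SIGMA_VOX)) + 2
    padded = np.pad(mask.data.astype(np.float64), pad)
    if mask.n_voxels > 1:
        try:
            smoothed = ndimage.gaussian_filter(
                padded, _MESH_SMOOTHING_SIGMA_VOX, mode="constant"
            )
            volume, area = _marching_mesh(smoothed, mask.spacing)
            return volume, area, False
        except (ValueError, RuntimeError):
            pass
        try:
            volume, area = _marching_mesh(padded, mask.spacing)
            return volume, area, False
        except (ValueError, RuntimeError):
            pass
    warnings.warn(
        "degenerate mask mesh; falling back to voxel-box volume/area",
        stacklevel=3,
    )
    volume = mask.n_voxels * mask.voxel_volume_mm3
    # Exposed-face area of the voxel-box surface.
    m = mask.data
    area = 0.0
    for axis, s in enumerate(mask.spacing):
        face_area = mask.voxel_volume_mm3 / s
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[axis] = slice(1, None)
        sl_b[axis] = slice(None, -1)
        interior = m[tuple(sl_a)] & m[tuple(sl_b)]
        area += (2 * int(m.sum()) - 2 * int(interior.sum())) * face_area
    return float(volume), float(area), True


def morphology_features(mask: VoiMask) -> dict[str, float]:
    """Mesh volume (cm³), surface area (cm²), sphericity and maximum 3D
    diameter (cm) of a binary mask.

    Sphericity = (36π V²)^(1/3) / A; the maximum 3D diameter is the
    largest pairwise distance between surface-voxel centers (chosen over
    mesh vertices for determinism independent of the mesher).
    """
    if mask.n_voxels == 0:
        raise ValueError("mask is empty")
    volume_mm3, area_mm2, degenerate = _mesh_volume_area(mask)
    sphericity = (36.0 * np.pi * volume_mm3**2) ** (1.0 / 3.0) / area_mm2

    surface = mask.data & ~ndimage.binary_erosion(mask.data)
    pts = np.argwhere(surface).astype(np.float64) * np.array(mask.spacing)
    if len(pts) == 1:
        diameter_mm = 0.0
    elif len(pts) <= 2000:
        diameter_mm = float(pdist(pts).max())
    else:
        try:
            hull = ConvexHull(pts)
            diameter_mm = float(pdist(pts[hull.vertices]).max())
        except QhullError:  # co-planar point sets
            diameter_mm = float(pdist(pts).max())

    return {
        "mesh_volume": volume_mm3 / 1000.0,
        "surface_area": area_mm2 / 100.0,
        "sphericity": float(min(sphericity, 1.0)) if degenerate else float(sphericity),
        "max_3d_diameter": diameter_mm / 10.0,
    }


# ---------------------------------------------------------------------------
# Intensity
# ---------------------------------------------------------------------------

def intensity_features(
    image: UptakeVolume, mask: VoiMask, disc: DiscretizedVolume
) -> dict[str, float]:
    """First-order features.

    Entropy (bits) and uniformity come from the discretized-level
    histogram; skewness, (un-excess, Pearson) kurtosis and standard
    deviation use population central moments of the raw in-mask values.
    A zero-variance region returns skewness and kurtosis of 0.
    """
    vals = mask.values_in(image).astype(np.float64)
    if vals.size < 2:
        raise ValueError("intensity features need at least two in-mask voxels")
    levels = disc.in_mask_levels()
    counts = np.bincount(levels)[1:]  # drop the sentinel bin
    q = counts[counts > 0] / levels.size
    entropy = float(-(q * np.log2(q)).sum())
    uniformity = float((q**2).sum())

    centered = vals - vals.mean()
    m2 = float((centered**2).mean())
    sd = float(np.sqrt(m2))
    if m2 == 0:
        skewness = kurtosis = 0.0
    else:
        skewness = float((centered**3).mean() / m2**1.5)
        kurtosis = float((centered**4).mean() / m2**2)
    return {
        "entropy": entropy,
        "uniformity": uniformity,
        "skewness": skewness,
        "kurtosis": kurtosis,
        "standard_deviation": sd,
    }


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def _glcm_matrix(disc: DiscretizedVolume) -> np.ndarray:
    """Direction-averaged, symmetric, normalized co-occurrence matrix."""
    levels = disc.levels
    ng = disc.n_levels
    matrices = []
    for off in DIRECTIONS_13:
        sl_a = tuple(
            slice(max(0, -o), levels.shape[ax] - max(0, o)) for ax, o in enumerate(off)
        )
        sl_b = tuple(
            slice(max(0, o), levels.shape[ax] + min(0, o)) for ax, o in enumerate(off)
        )
        a = levels[sl_a].ravel()
        b = levels[sl_b].ravel()
        valid = (a > 0) & (b > 0)
        if not valid.any():
            continue
        a, b = a[valid] - 1, b[valid] - 1
        counts = np.bincount(a * ng + b, minlength=ng * ng).reshape(ng, ng)
        counts = counts + counts.T  # symmetric pairs
        matrices.append(counts / counts.sum())
    if not matrices:
        raise ValueError("no in-mask voxel pairs in any direction")
    return np.mean(matrices, axis=0)


def glcm_features(disc: DiscretizedVolume) -> dict[str, float]:
    """Six features of the direction-averaged GLCM.

    With marginal mean μ and variance σ² of the averaged matrix
    ``p(i, j)``: contrast Σ(i−j)²p, correlation Σ(i−μ)(j−μ)p/σ²
    (defined as 1 for a constant region), inverse difference
    Σp/(1+|i−j|), normalized inverse difference Σp/(1+|i−j|/N_g), joint
    energy Σp² and joint entropy −Σ p log₂ p.
    """
    p = _glcm_matrix(disc)
    ng = p.shape[0]
    i = np.arange(1, ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    pi = p.sum(axis=1)
    mu = float((i * pi).sum())
    sigma2 = float(((i - mu) ** 2 * pi).sum())

    contrast = float((((ii - jj) ** 2) * p).sum())
    if sigma2 > 0:
        correlation = float((((ii - mu) * (jj - mu)) * p).sum() / sigma2)
    else:
        warnings.warn("constant region: GLCM correlation defined as 1", stacklevel=2)
        correlation = 1.0
    inv_diff = float((p / (1.0 + np.abs(ii - jj))).sum())
    norm_inv_diff = float((p / (1.0 + np.abs(ii - jj) / ng)).sum())
    joint_energy = float((p**2).sum())
    nz = p[p > 0]
    joint_entropy = float(-(nz * np.log2(nz)).sum())
    return {
        "glcm_contrast": contrast,
        "glcm_correlation": correlation,
        "glcm_inverse_difference": inv_diff,
        "glcm_normalized_inverse_difference": norm_inv_diff,
        "glcm_joint_energy": joint_energy,
        "glcm_joint_entropy": joint_entropy,
    }


# ---------------------------------------------------------------------------
# NGTDM
# ---------------------------------------------------------------------------

def _ngtdm_table(disc: DiscretizedVolume) -> tuple[np.ndarray, np.ndarray, int]:
    """Per-level probabilities p_i and summed deviations s_i.

    Voxels with no in-mask 26-neighbor are excluded from the count N.
    Returns (p, s, N) with arrays indexed by level 1..n_levels at
    positions 0..n_levels-1.
    """
    levels = disc.levels
    mask = disc.mask.data
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0.0
    nbr_sum = ndimage.correlate(
        (levels * mask).astype(np.float64), kernel, mode="constant"
    )
    nbr_cnt = ndimage.correlate(mask.astype(np.float64), kernel, mode="constant")
    valid = mask & (nbr_cnt > 0.5)
    if not valid.any():
        raise ValueError("no in-mask voxel has an in-mask neighbor")
    lv = levels[valid]
    dev = np.abs(lv - nbr_sum[valid] / nbr_cnt[valid])
    ng = disc.n_levels
    n_total = int(valid.sum())
    n_i = np.bincount(lv, minlength=ng + 1)[1:]
    s_i = np.bincount(lv, weights=dev, minlength=ng + 1)[1:]
    return n_i / n_total, s_i, n_total


def ngtdm_features(disc: DiscretizedVolume) -> dict[str, float]:
    """Busyness, coarseness, complexity, contrast and strength of the NGTDM."""
    p, s, n_total = _ngtdm_table(disc)
    ng = len(p)
    i = np.arange(1, ng + 1, dtype=np.float64)
    present = p > 0
    ngp = int(present.sum())
    ps = p * s
    sum_ps = float(ps.sum())
    sum_s = float(s.sum())

    coarseness = 1.0 / sum_ps if sum_ps > 0 else COARSENESS_CAP
    coarseness = min(coarseness, COARSENESS_CAP)

    ii = i[present]
    pp = p[present]
    ss = s[present]
    psp = ps[present]
    di = ii[:, None] - ii[None, :]

    if ngp > 1:
        contrast = float(
            (pp[:, None] * pp[None, :] * di**2).sum() / (ngp * (ngp - 1))
        ) * (sum_s / n_total)
        busy_den = float(np.abs(ii[:, None] * pp[:, None] - ii[None, :] * pp[None, :])[
            ~np.eye(ngp, dtype=bool)
        ].sum())
        busyness = sum_ps / busy_den if busy_den > 0 else 0.0
        off = ~np.eye(ngp, dtype=bool)
        complexity = float(
            (np.abs(di) * (psp[:, None] + psp[None, :]) / (pp[:, None] + pp[None, :]))[
                off
            ].sum()
        ) / n_total
        strength_num = float(((pp[:, None] + pp[None, :]) * di**2)[off].sum())
        strength = strength_num / sum_s if sum_s > 0 else 0.0
    else:
        contrast = 0.0
        busyness = 0.0
        complexity = 0.0
        strength = 0.0
    return {
        "ngtdm_busyness": busyness,
        "ngtdm_coarseness": coarseness,
        "ngtdm_complexity": complexity,
        "ngtdm_contrast": contrast,
        "ngtdm_strength": strength,
    }


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def extract_features(
    image: UptakeVolume,
    mask: VoiMask,
    *,
    target_spacing_mm: float = 2.0,
    bin_width: float = 0.5,
) -> dict:
    """Run the full feature chain and return the 20 named features.

    Resampling → discretization → morphology / intensity / GLCM / NGTDM.
    The returned dict carries the 20 features in report order plus a
    ``provenance`` block (spacing, bin width, level count).
    """
    img_r, mask_r = resample_isotropic(image, mask, target_mm=target_spacing_mm)
    disc = discretize_fbw(img_r, mask_r, bin_width=bin_width)
    out: dict = {}
    for stage, result in (
        ("morphology", lambda: morphology_features(mask_r)),
        ("intensity", lambda: intensity_features(img_r, mask_r, disc)),
        ("glcm", lambda: glcm_features(disc)),
        ("ngtdm", lambda: ngtdm_features(disc)),
    ):
        try:
            out.update(result())
        except Exception as exc:  # noqa: BLE001 - annotate the failing stage
            raise RuntimeError(f"feature stage {stage!r} failed: {exc}") from exc
    ordered = {name: out[name] for name in FEATURE_NAMES}
    ordered["provenance"] = {
        "target_spacing_mm": target_spacing_mm,
        "bin_width": bin_width,
        "n_levels": disc.n_levels,
        "n_mask_voxels": mask_r.n_voxels,
    }
    return ordered
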