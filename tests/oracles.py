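"""Independent brute-force reference implementations used only by tests.

Everything here is written with plain Python loops and deliberately
shares no code with the package, so it can serve as an oracle for the
vectorized implementations.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

DIRS_13 = [
    (di, dj, dk)
    for di in (-1, 0, 1)
    for dj in (-1, 0, 1)
    for dk in (-1, 0, 1)
    if (di, dj, dk) > (0, 0, 0)
]

NEIGHBORS_26 = [
    (di, dj, dk)
    for di in (-1, 0, 1)
    for dj in (-1, 0, 1)
    for dk in (-1, 0, 1)
    if (di, dj, dk) != (0, 0, 0)
]


def brute_glcm_features(levels: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    """Direction-averaged symmetric GLCM features by pair enumeration."""
    ng = int(levels[mask].max())
    shape = mask.shape
    mats = []
    for d in DIRS_13:
        counts = [[0.0] * ng for _ in range(ng)]
        total = 0
        for idx in zip(*np.nonzero(mask)):
            j = tuple(int(idx[k]) + d[k] for k in range(3))
            if all(0 <= j[k] < shape[k] for k in range(3)) and mask[j]:
                a = int(levels[idx]) - 1
                b = int(levels[j]) - 1
                counts[a][b] += 1.0
                counts[b][a] += 1.0
                total += 2
        if total:
            mats.append([[c / total for c in row] for row in counts])
    assert mats, "no co-occurring pairs"
    p = [[sum(m[i][j] for m in mats) / len(mats) for j in range(ng)]
         for i in range(ng)]

    mu = sum((i + 1) * p[i][j] for i in range(ng) for j in range(ng))
    sigma2 = sum((i + 1 - mu) ** 2 * p[i][j] for i in range(ng) for j in range(ng))
    contrast = sum((i - j) ** 2 * p[i][j] for i in range(ng) for j in range(ng))
    if sigma2 > 0:
        correlation = sum(
            (i + 1 - mu) * (j + 1 - mu) * p[i][j]
            for i in range(ng) for j in range(ng)
        ) / sigma2
    else:
        correlation = 1.0
    inv_diff = sum(p[i][j] / (1 + abs(i - j)) for i in range(ng) for j in range(ng))
    nid = sum(p[i][j] / (1 + abs(i - j) / ng) for i in range(ng) for j in range(ng))
    energy = sum(p[i][j] ** 2 for i in range(ng) for j in range(ng))
    entropy = -sum(
        p[i][j] * math.log2(p[i][j])
        for i in range(ng) for j in range(ng) if p[i][j] > 0
    )
    return {
        "glcm_contrast": contrast,
        "glcm_correlation": correlation,
        "glcm_inverse_difference": inv_diff,
        "glcm_normalized_inverse_difference": nid,
        "glcm_joint_energy": energy,
        "glcm_joint_entropy": entropy,
    }


def brute_ngtdm_features(levels: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    """NGTDM features by per-voxel neighborhood enumeration."""
    ng = int(levels[mask].max())
    shape = mask.shape
    n_i = [0] * (ng + 1)
    s_i = [0.0] * (ng + 1)
    n_total = 0
    for idx in zip(*np.nonzero(mask)):
        nbrs = []
        for d in NEIGHBORS_26:
            j = tuple(int(idx[k]) + d[k] for k in range(3))
            if all(0 <= j[k] < shape[k] for k in range(3)) and mask[j]:
                nbrs.append(int(levels[j]))
        if not nbrs:
            continue
        lv = int(levels[idx])
        n_total += 1
        n_i[lv] += 1
        s_i[lv] += abs(lv - sum(nbrs) / len(nbrs))
    assert n_total > 0
    p = [n / n_total for n in n_i]
    present = [i for i in range(1, ng + 1) if p[i] > 0]
    ngp = len(present)
    sum_ps = sum(p[i] * s_i[i] for i in present)
    sum_s = sum(s_i[i] for i in present)

    coarseness = min(1.0 / sum_ps if sum_ps > 0 else 1e6, 1e6)
    if ngp > 1:
        contrast = (
            sum(p[i] * p[j] * (i - j) ** 2 for i in present for j in present)
            / (ngp * (ngp - 1))
        ) * (sum_s / n_total)
        busy_den = sum(
            abs(i * p[i] - j * p[j]) for i in present for j in present if i != j
        )
        busyness = sum_ps / busy_den if busy_den > 0 else 0.0
        complexity = sum(
            abs(i - j) * (p[i] * s_i[i] + p[j] * s_i[j]) / (p[i] + p[j])
            for i in present for j in present if i != j
        ) / n_total
        strength_num = sum(
            (p[i] + p[j]) * (i - j) ** 2 for i in present for j in present if i != j
        )
        strength = strength_num / sum_s if sum_s > 0 else 0.0
    else:
        contrast = busyness = complexity = strength = 0.0
    return {
        "ngtdm_busyness": busyness,
        "ngtdm_coarseness": coarseness,
        "ngtdm_complexity": complexity,
        "ngtdm_contrast": contrast,
        "ngtdm_strength": strength,
    }


def brute_intensity_features(values: np.ndarray, levels: np.ndarray) -> dict[str, float]:
    """First-order features by direct summation."""
    counts: dict[int, int] = {}
    for lv in levels:
        counts[int(lv)] = counts.get(int(lv), 0) + 1
    n = len(levels)
    q = [c / n for c in counts.values()]
    entropy = -sum(qk * math.log2(qk) for qk in q)
    uniformity = sum(qk**2 for qk in q)

    vals = [float(v) for v in values]
    m = sum(vals) / len(vals)
    m2 = sum((v - m) ** 2 for v in vals) / len(vals)
    sd = math.sqrt(m2)
    if m2 == 0:
        skew = kurt = 0.0
    else:
        skew = (sum((v - m) ** 3 for v in vals) / len(vals)) / m2**1.5
        kurt = (sum((v - m) ** 4 for v in vals) / len(vals)) / m2**2
    return {
        "entropy": entropy,
        "uniformity": uniformity,
        "skewness": skew,
        "kurtosis": kurt,
        "standard_deviation": sd,
    }


def brute_wilcoxon_p(diffs) -> tuple[float, float]:
    """Exact two-sided signed-rank p by enumerating all 2^n sign patterns.

    Midranks computed by hand (no scipy).  Returns (W+, p).
    """
    d = [float(x) for x in diffs if x != 0]
    n = len(d)
    absd = sorted((abs(x), i) for i, x in enumerate(d))
    ranks = [0.0] * n
    i = 0
    pos = 1
    while i < n:
        j = i
        while j < n and absd[j][0] == absd[i][0]:
            j += 1
        mid = (pos + (pos + (j - i) - 1)) / 2.0
        for k in range(i, j):
            ranks[absd[k][1]] = mid
        pos += j - i
        i = j
    w_obs = sum(r for r, x in zip(ranks, d) if x > 0)
    ws = []
    for signs in itertools.product((0, 1), repeat=n):
        ws.append(sum(r for r, s in zip(ranks, signs) if s))
    total = len(ws)
    p_le = sum(1 for w in ws if w <= w_obs + 1e-12) / total
    p_ge = sum(1 for w in ws if w >= w_obs - 1e-12) / total
    return w_obs, min(1.0, 2.0 * min(p_le, p_ge))


def blurred_sphere_center_value(radius_mm: float, fwhm_mm: float) -> float:
    """Closed-form value at the center of a unit sphere convolved with an
    isotropic Gaussian: erf(R/σ√2) − sqrt(2/π)(R/σ)exp(−R²/2σ²)."""
    sigma = fwhm_mm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    r = radius_mm / sigma
    return math.erf(r / math.sqrt(2.0)) - math.sqrt(2.0 / math.pi) * r * math.exp(
        -(r**2) / 2.0
    )
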