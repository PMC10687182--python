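"""GLCM Haralick texture features of masked detection images.

Each sample image (AC or RT, restricted to the fruit mask) is linearly
quantized to a small number of gray levels; a symmetric, normalized
gray-level co-occurrence matrix is accumulated for pixel pairs at
distance 1 along each of the four directions 0, 45, 90 and 135 degrees,
counting only pairs whose both pixels lie inside the mask; and the 14
classical Haralick statistics are computed per direction, giving a
56-dimensional feature vector per image.

Entropies use base-2 logarithms with 0*log(0) = 0.  Sum variance is taken
about the sum average (the familiar erratum in the original feature
table).  Statistics that are undefined on degenerate matrices (zero
marginal variance, vanishing entropies) fall back to 0 so vectors stay
finite even for constant regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

__all__ = [
    "GlcmSpec",
    "FeatureVector",
    "HARALICK_NAMES",
    "ANGLES",
    "feature_names",
    "quantize_masked",
    "glcm",
    "haralick14",
    "feature_vector",
]

#: Pair offsets (drow, dcol) per angle, matching the usual GLCM convention.
ANGLES = (0, 45, 90, 135)
_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}

HARALICK_NAMES = (
    "asm",
    "contrast",
    "correlation",
    "variance",
    "idm",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "entropy",
    "difference_variance",
    "difference_entropy",
    "imc1",
    "imc2",
    "mcc",
)


@dataclass(frozen=True)
class GlcmSpec:
    """Co-occurrence settings: distance 1, four angles, symmetric+normalized."""

    distance: int = 1
    angles: tuple[int, ...] = ANGLES
    levels: int = 32
    symmetric: bool = True
    normalized: bool = True

    def __post_init__(self) -> None:
        if self.distance != 1:
            raise ValueError("pair distance is fixed to 1 pixel")
        if tuple(self.angles) != ANGLES:
            raise ValueError(f"angles are fixed to {ANGLES}")
        if self.levels < 2:
            raise ValueError("need at least 2 gray levels")


@dataclass(frozen=True)
class FeatureVector:
    """56 Haralick features (14 statistics x 4 angles) of one sample image."""

    values: np.ndarray
    feature_names: tuple[str, ...]
    sample_id: str = "sample"
    label: str | None = None
    degree: str | None = None
    source_image: str | None = None

    def __post_init__(self) -> None:
        if len(self.values) != 56 or len(self.feature_names) != 56:
            raise ValueError("a feature vector has exactly 56 entries")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")


def feature_names() -> tuple[str, ...]:
    """The 56 names '<stat>_<angle>', grouped by angle in 0,45,90,135 order."""
    return tuple(f"{stat}_{ang}" for ang in ANGLES for stat in HARALICK_NAMES)


def quantize_masked(
    image: np.ndarray, mask: np.ndarray, levels: int
) -> tuple[np.ndarray, np.ndarray]:
    """Linear min-max quantization of masked pixels into {0..levels-1}.

    Returns the integer image (0 outside the mask) and the boolean
    valid-pixel map.  A constant masked region maps entirely to level 0.
    """
    if levels < 2:
        raise ValueError("need at least 2 gray levels")
    image = np.asarray(image, dtype=np.float64)
    valid = np.asarray(mask, dtype=bool)
    if image.shape != valid.shape:
        raise ValueError("image and mask must share a shape")
    if not valid.any():
        raise ValueError("mask is empty")
    vals = image[valid]
    lo, hi = vals.min(), vals.max()
    quant = np.zeros(image.shape, dtype=np.intp)
    if hi > lo:
        scaled = (image[valid] - lo) / (hi - lo) * levels
        quant[valid] = np.minimum(scaled.astype(np.intp), levels - 1)
    return quant, valid


def glcm(
    quantized: np.ndarray,
    valid: np.ndarray,
    angle: int,
    distance: int = 1,
    levels: int | None = None,
    symmetric: bool = True,
    normalized: bool = True,
) -> np.ndarray:
    """Co-occurrence matrix for one direction, counting valid pairs only.

    A pair contributes when both its pixels lie inside the valid map.  With
    ``symmetric`` the transpose is added; with ``normalized`` the counts are
    divided by their sum.
    """
    if angle not in _OFFSETS:
        raise ValueError(f"angle must be one of {ANGLES}, got {angle}")
    quantized = np.asarray(quantized)
    valid = np.asarray(valid, dtype=bool)
    if levels is None:
        levels = int(quantized[valid].max()) + 1 if valid.any() else 2
    dr, dc = (distance * d for d in _OFFSETS[angle])

    h, w = quantized.shape
    r0s, r0e = max(0, -dr), min(h, h - dr)
    c0s, c0e = max(0, -dc), min(w, w - dc)
    a = quantized[r0s:r0e, c0s:c0e]
    b = quantized[r0s + dr : r0e + dr, c0s + dc : c0e + dc]
    ok = valid[r0s:r0e, c0s:c0e] & valid[r0s + dr : r0e + dr, c0s + dc : c0e + dc]
    if not ok.any():
        raise ValueError(f"no valid pixel pairs at angle {angle}")
    pairs = a[ok] * levels + b[ok]
    counts = np.bincount(pairs, minlength=levels * levels).reshape(levels, levels)
    counts = counts.astype(np.float64)
    if symmetric:
        counts = counts + counts.T
    if normalized:
        counts /= counts.sum()
    return counts


def _entropy2(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def haralick14(p: np.ndarray) -> np.ndarray:
    """The 14 Haralick statistics of a normalized symmetric GLCM, fixed order.

    Order: ASM, contrast, correlation, sum-of-squares variance, inverse
    difference moment, sum average, sum variance, sum entropy, entropy,
    difference variance, difference entropy, information measures of
    correlation 1 and 2, maximal correlation coefficient.
    """
    p = np.asarray(p, dtype=np.float64)
    if p.ndim != 2 or p.shape[0] != p.shape[1]:
        raise ValueError("GLCM must be square")
    if not np.isclose(p.sum(), 1.0, atol=1e-8):
        raise ValueError("GLCM must be normalized to sum 1")
    n = p.shape[0]
    i = np.arange(n, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float((i * px).sum())
    mu_y = float((i * py).sum())
    var_x = float(((i - mu_x) ** 2 * px).sum())
    var_y = float(((i - mu_y) ** 2 * py).sum())

    asm = float((p**2).sum())
    contrast = float(((ii - jj) ** 2 * p).sum())
    if var_x > 0 and var_y > 0:
        correlation = float(((ii * jj * p).sum() - mu_x * mu_y) / np.sqrt(var_x * var_y))
    else:
        correlation = 0.0
    variance = var_x  # sum-of-squares variance about the row-marginal mean
    idm = float((p / (1.0 + (ii - jj) ** 2)).sum())

    # p_{x+y}(k), k = 0..2n-2 and p_{x-y}(k), k = 0..n-1
    psum = np.bincount((ii + jj).astype(int).ravel(), weights=p.ravel(), minlength=2 * n - 1)
    pdiff = np.bincount(
        np.abs(ii - jj).astype(int).ravel(), weights=p.ravel(), minlength=n
    )
    k_sum = np.arange(psum.size, dtype=np.float64)
    k_diff = np.arange(pdiff.size, dtype=np.float64)
    sum_average = float((k_sum * psum).sum())
    sum_variance = float(((k_sum - sum_average) ** 2 * psum).sum())
    sum_entropy = _entropy2(psum)
    entropy = _entropy2(p.ravel())
    diff_mean = float((k_diff * pdiff).sum())
    difference_variance = float(((k_diff - diff_mean) ** 2 * pdiff).sum())
    difference_entropy = _entropy2(pdiff)

    hx, hy = _entropy2(px), _entropy2(py)
    outer = np.outer(px, py)
    nz = (p > 0) & (outer > 0)
    hxy1 = float(-(p[nz] * np.log2(outer[nz])).sum())
    nz2 = outer > 0
    hxy2 = float(-(outer[nz2] * np.log2(outer[nz2])).sum())
    denom = max(hx, hy)
    imc1 = float((entropy - hxy1) / denom) if denom > 0 else 0.0
    arg = 1.0 - np.exp(-2.0 * (hxy2 - entropy))
    imc2 = float(np.sqrt(max(arg, 0.0)))

    mcc = _max_correlation_coefficient(p, px, py)
    return np.array(
        [
            asm,
            contrast,
            correlation,
            variance,
            idm,
            sum_average,
            sum_variance,
            sum_entropy,
            entropy,
            difference_variance,
            difference_entropy,
            imc1,
            imc2,
            mcc,
        ]
    )


def _max_correlation_coefficient(p: np.ndarray, px: np.ndarray, py: np.ndarray) -> float:
    """Square root of the second-largest eigenvalue of the Q matrix.

    Rows/columns with empty marginals are dropped; if fewer than two levels
    remain (constant image) the statistic is defined as 0.
    """
    keep = (px > 0) & (py > 0)
    if keep.sum() < 2:
        return 0.0
    psub = p[np.ix_(keep, keep)]
    pxs = px[keep]
    pys = py[keep]
    # Q[i,j] = sum_k p(i,k) * p(j,k) / (px(i) * py(k))
    q = (psub / pxs[:, None]) @ (psub / pys[None, :]).T
    try:
        eig = np.sort(np.real(linalg.eigvals(q)))
    except linalg.LinAlgError:  # pragma: no cover - scipy eig rarely fails
        return 0.0
    second = eig[-2] if eig.size >= 2 else 0.0
    return float(np.sqrt(max(second, 0.0)))


def feature_vector(
    image: np.ndarray,
    mask: np.ndarray,
    spec: GlcmSpec = GlcmSpec(),
    *,
    sample_id: str = "sample",
    label: str | None = None,
    degree: str | None = None,
    source_image: str | None = None,
) -> FeatureVector:
    """Full 56-feature Haralick vector of a masked image.

    Angles are concatenated in the fixed order 0, 45, 90, 135 degrees, with
    the 14 statistics in :data:`HARALICK_NAMES` order inside each block.
    """
    quant, valid = quantize_masked(image, mask, spec.levels)
    values = np.concatenate(
        [
            haralick14(
                glcm(
                    quant,
                    valid,
                    angle,
                    distance=spec.distance,
                    levels=spec.levels,
                    symmetric=spec.symmetric,
                    normalized=spec.normalized,
                )
            )
            for angle in spec.angles
        ]
    )
    return FeatureVector(
        values=values,
        feature_names=feature_names(),
        sample_id=sample_id,
        label=label,
        degree=degree,
        source_image=source_image,
    )
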