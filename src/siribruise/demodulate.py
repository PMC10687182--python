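"""Three-phase demodulation (TPD) of sinusoidal pattern triplets.

Given three pattern images with equally spaced phase offsets
(-2*pi/3, 0, +2*pi/3), the planar and modulated components are recovered
pixel-by-pixel:

    I_DC = (I1 + I2 + I3) / 3
    I_AC = (sqrt(2)/3) * sqrt((I1-I2)^2 + (I1-I3)^2 + (I2-I3)^2)

For an ideal sinusoid these are exact at every pixel regardless of the
carrier phase, and the pairwise subtractions cancel any offset common to
the three images.  The ratio image RT = I_AC / I_DC flattens the
illumination field (surface curvature and reflectance cancel) and raises
bruise contrast, which is why it is the preferred detection image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .synthetic_scene import PatternTriplet

__all__ = [
    "DemodulationResult",
    "tpd_demodulate",
    "ratio_image",
    "gaussian_lowpass",
    "demodulate_triplet",
]


@dataclass(frozen=True)
class DemodulationResult:
    """Floating-point DC, AC (low-pass filtered) and RT images of one sample."""

    dc_image: np.ndarray
    ac_image: np.ndarray
    rt_image: np.ndarray
    frequency: float
    filter_sigma: float
    sample_id: str = "sample"
    degree: str | None = None


def _as_three_arrays(triplet) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    images = triplet.images if isinstance(triplet, PatternTriplet) else tuple(triplet)
    if len(images) != 3:
        raise ValueError(f"three-phase demodulation needs exactly 3 images, got {len(images)}")
    arrs = tuple(np.asarray(im, dtype=np.float64) for im in images)
    shapes = {a.shape for a in arrs}
    if len(shapes) != 1:
        raise ValueError(f"pattern images must share one shape, got {shapes}")
    return arrs


def tpd_demodulate(triplet) -> tuple[np.ndarray, np.ndarray]:
    """Recover the (DC, AC) images from a pattern triplet.

    Accepts a :class:`~siribruise.synthetic_scene.PatternTriplet` or any
    sequence of three equally shaped arrays; computation is in float64
    regardless of the input bit depth.
    """
    i1, i2, i3 = _as_three_arrays(triplet)
    dc = (i1 + i2 + i3) / 3.0
    ac = (np.sqrt(2.0) / 3.0) * np.sqrt(
        (i1 - i2) ** 2 + (i1 - i3) ** 2 + (i2 - i3) ** 2
    )
    return dc, ac


def ratio_image(dc_image: np.ndarray, ac_image: np.ndarray, eps: float = 1e-9) -> np.ndarray:
    """RT = AC / DC with a guard: pixels where DC <= eps map to 0.

    Background pixels off the fruit have (near-)zero DC; they are masked
    downstream, so a hard zero is the right degenerate value.
    """
    dc = np.asarray(dc_image, dtype=np.float64)
    ac = np.asarray(ac_image, dtype=np.float64)
    if dc.shape != ac.shape:
        raise ValueError("DC and AC images must share a shape")
    rt = np.zeros_like(dc)
    ok = dc > eps
    rt[ok] = ac[ok] / dc[ok]
    return rt


def gaussian_lowpass(
    image: np.ndarray, sigma: float, mask: np.ndarray | None = None
) -> np.ndarray:
    """2-D Gaussian smoothing with reflective boundaries; sigma=0 is identity.

    With ``mask`` the smoothing is restricted to the masked domain by
    normalized convolution (smooth(image*mask)/smooth(mask)), which keeps
    the dark background from bleeding into the fruit rim; pixels outside
    the mask are set to 0.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    image = np.asarray(image, dtype=np.float64)
    if sigma == 0:
        out = image.copy()
        if mask is not None:
            out[~np.asarray(mask, dtype=bool)] = 0.0
        return out
    if mask is None:
        return ndimage.gaussian_filter(image, sigma=sigma, mode="reflect", truncate=6.0)
    m = np.asarray(mask, dtype=np.float64)
    num = ndimage.gaussian_filter(image * m, sigma=sigma, mode="reflect", truncate=6.0)
    den = ndimage.gaussian_filter(m, sigma=sigma, mode="reflect", truncate=6.0)
    out = np.zeros_like(image)
    inside = m > 0
    out[inside] = num[inside] / den[inside]
    return out


def demodulate_triplet(
    triplet,
    filter_sigma: float = 2.0,
    eps: float = 1e-9,
    filter_before_ratio: bool = True,
    mask: np.ndarray | None = None,
) -> DemodulationResult:
    """Full demodulation of one sample: DC, denoised AC, and RT.

    The Gaussian low-pass (default sigma 2 px) is applied to the AC image
    before the ratio is formed; set ``filter_before_ratio=False`` to form
    RT from the raw AC instead and filter only the stored AC.  Passing a
    fruit ``mask`` (mask-then-filter order) restricts the smoothing to the
    fruit domain so the dark background does not depress the rim.
    """
    dc, ac_raw = tpd_demodulate(triplet)
    ac = gaussian_lowpass(ac_raw, filter_sigma, mask=mask)
    rt = ratio_image(dc, ac if filter_before_ratio else ac_raw, eps=eps)
    freq = 0.0
    sid, degree = "sample", None
    if isinstance(triplet, PatternTriplet):
        freq = triplet.illumination.spatial_frequency
        sid, degree = triplet.sample_id, triplet.degree
    return DemodulationResult(
        dc_image=dc,
        ac_image=ac,
        rt_image=rt,
        frequency=freq,
        filter_sigma=filter_sigma,
        sample_id=sid,
        degree=degree,
    )
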