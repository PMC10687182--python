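"""Ground-truthed fruit phantoms and sinusoidal pattern rendering.

Structured-illumination reflectance imaging (SIRI) projects sinusoidal
fringe patterns onto a sample and records one image per phase offset.  A
pattern image follows

    I_n(x, y) = I_DC(x, y) + I_AC(x, y) * cos(2*pi*f_x*x + 2*pi*f_y*y + phi_n)

where the planar (DC) term is the ordinary diffuse-illumination image and
the modulated (AC) term carries depth-resolved contrast: the depth of
tissue interrogation shrinks as the spatial frequency grows, so a
subsurface bruise appears in AC but not DC.

This module emulates such acquisitions of a fruit with an optional
subsurface bruise so that the downstream demodulation / segmentation /
texture / classification chain can be exercised with known ground truth:

* a bright elliptical fruit on a dark background, with a radial cosine
  vignette darkening the rim (surface curvature);
* a per-pixel modulation transfer that decays exponentially with spatial
  frequency and carries a smooth multiplicative texture field (subsurface
  scattering heterogeneity) — the texture survives the AC/DC ratio while
  the reflectance vignette cancels;
* a bruise disk whose AC attenuation depth depends on the bruise degree
  (S0 sound .. S3 severe) and on frequency through a single-peak
  rise-then-fall contrast curve;
* additive Gaussian sensor noise and optional 8-bit quantization.

Fringes vary along image columns only (f_y = 0); x is the column index
converted to meters through the pixel pitch, origin at the top-left.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "DEGREES",
    "GeometryError",
    "IlluminationSpec",
    "NoiseSpec",
    "PhantomScene",
    "PatternTriplet",
    "make_phantom",
    "render_triplet",
    "make_dataset",
]

TWO_PI = 2.0 * math.pi

#: Bruise degrees: S0 sound, then mild / moderate / severe static-load bruises.
DEGREES = ("S0", "S1", "S2", "S3")

#: Default AC-attenuation depth (unitless, at the peak frequency) per degree.
DEFAULT_BRUISE_DEPTHS = {"S0": 0.0, "S1": 0.25, "S2": 0.45, "S3": 0.65}

#: Default bruise radius in pixels per degree (0 for sound fruit).  The
#: contusion footprint follows the ~3 cm pressure probe on an ~8 cm fruit
#: (roughly a third of the fruit semi-axis), growing mildly with load.
DEFAULT_BRUISE_RADII = {"S0": 0.0, "S1": 24.0, "S2": 29.0, "S3": 34.0}


class GeometryError(ValueError):
    """Raised when a bruise does not fit strictly inside the fruit ellipse."""


@dataclass(frozen=True)
class IlluminationSpec:
    """Sinusoidal illumination: spatial frequency, phase offsets, DC/AC counts.

    ``spatial_frequency`` is in cycles per meter along columns; ``frequency_y``
    is kept for completeness and defaults to 0 (fringes along one axis only).
    ``carrier_phase`` shifts all three patterns by a common angle, which lets
    tests sweep the carrier phase without breaking the equal spacing of the
    three offsets.
    """

    spatial_frequency: float
    frequency_y: float = 0.0
    phase_offsets: tuple[float, float, float] = (-TWO_PI / 3, 0.0, TWO_PI / 3)
    illum_dc: float = 255.0 / 2.0
    illum_ac: float = 255.0 / 2.0
    carrier_phase: float = 0.0

    def validate(self) -> None:
        if self.spatial_frequency < 0:
            raise ValueError(f"spatial frequency must be >= 0, got {self.spatial_frequency}")
        if len(self.phase_offsets) != 3:
            raise ValueError("exactly three phase offsets are required")
        offs = np.sort(np.mod(self.phase_offsets, TWO_PI))
        gaps = np.diff(np.concatenate([offs, [offs[0] + TWO_PI]]))
        if np.any(gaps < 1e-9):
            raise ValueError("phase offsets must be distinct modulo 2*pi")
        if not np.allclose(gaps, TWO_PI / 3, atol=1e-9):
            raise ValueError("phase offsets must be equally spaced (2*pi/3 apart)")
        if not (0.0 <= self.illum_ac <= self.illum_dc):
            raise ValueError("need 0 <= I_AC <= I_DC for a nonnegative ideal pattern")


@dataclass(frozen=True)
class NoiseSpec:
    """Additive Gaussian sensor noise (in counts) and optional 8-bit rounding."""

    gaussian_sigma: float = 1.0
    quantize: bool = True
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.gaussian_sigma < 0:
            raise ValueError("gaussian_sigma must be >= 0")


@dataclass(frozen=True)
class PhantomScene:
    """A fruit phantom with known geometry, optics and bruise ground truth.

    ``dc_reflectance_map`` is the per-pixel diffuse reflectance in [0, 1]
    (zero outside the fruit ellipse, vignetted toward the rim).  The
    modulation transfer at spatial frequency ``f`` is
    ``modulation_texture * exp(-f / mtf_scale)`` and the bruise attenuates
    the AC amplitude by ``bruise_contrast(f) * bruise_profile`` inside the
    bruise disk.
    """

    width: int
    height: int
    pixel_pitch: float  # meters per pixel
    fruit_center: tuple[float, float]  # (row, col)
    fruit_axes: tuple[float, float]  # semi-axes (row, col) in pixels
    dc_reflectance_map: np.ndarray
    modulation_texture: np.ndarray
    mtf_scale: float  # cycles/m e-folding of the modulation transfer
    bruise_center: tuple[float, float]  # (row, col)
    bruise_radius: float  # pixels
    bruise_degree: str
    bruise_depth: float  # peak AC attenuation in [0, 1]
    bruise_peak_frequency: float  # cycles/m
    bruise_profile: np.ndarray  # smooth [0,1] spatial profile, 0 outside disk

    def __post_init__(self) -> None:
        r = self.dc_reflectance_map
        if r.shape != (self.height, self.width):
            raise ValueError("dc_reflectance_map shape mismatch")
        if r.min() < 0 or r.max() > 1:
            raise ValueError("dc_reflectance_map must lie in [0, 1]")
        if self.bruise_degree not in DEGREES:
            raise ValueError(f"unknown bruise degree {self.bruise_degree!r}")

    @property
    def fruit_mask(self) -> np.ndarray:
        """Ground-truth boolean support of the fruit ellipse."""
        rho = self._elliptical_radius()
        return rho <= 1.0

    def _elliptical_radius(self) -> np.ndarray:
        rr, cc = np.mgrid[0 : self.height, 0 : self.width]
        ar, ac = self.fruit_axes
        return np.hypot((rr - self.fruit_center[0]) / ar, (cc - self.fruit_center[1]) / ac)

    def modulation_map(self, frequency: float) -> np.ndarray:
        """Per-pixel modulation transfer at ``frequency`` (cycles/m)."""
        return self.modulation_texture * math.exp(-frequency / self.mtf_scale)

    def bruise_contrast(self, frequency: float) -> float:
        """Frequency-dependent AC attenuation depth inside the bruise.

        Single-peak rise-then-fall curve ``depth * (f/fp) * exp(1 - f/fp)``:
        zero at f=0, maximum ``depth`` at the peak frequency, decaying beyond.
        """
        if self.bruise_depth == 0.0 or frequency <= 0.0:
            return 0.0
        u = frequency / self.bruise_peak_frequency
        return float(self.bruise_depth * u * math.exp(1.0 - u))

    def bruise_attenuation_map(self, frequency: float) -> np.ndarray:
        return self.bruise_contrast(frequency) * self.bruise_profile


@dataclass(frozen=True)
class PatternTriplet:
    """Three co-registered pattern images at one frequency and known phases."""

    images: tuple[np.ndarray, np.ndarray, np.ndarray]
    illumination: IlluminationSpec
    sample_id: str = "sample"
    degree: str | None = None

    def __post_init__(self) -> None:
        if len(self.images) != 3:
            raise ValueError("a pattern triplet needs exactly three images")
        shapes = {im.shape for im in self.images}
        if len(shapes) != 1:
            raise ValueError(f"pattern images must share one shape, got {shapes}")


def _smoothstep(t: np.ndarray) -> np.ndarray:
    t = np.clip(t, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def make_phantom(
    degree: str,
    *,
    seed: int,
    width: int = 256,
    height: int = 256,
    pixel_pitch: float = 5e-4,
    bruise_depths: dict[str, float] | None = None,
    bruise_radii: dict[str, float] | None = None,
    peak_frequency: float = 150.0,
    mtf_scale: float = 350.0,
    vignette_strength: float = 0.3,
    vignette_jitter: float = 0.15,
    illumination_tilt: float = 0.15,
    texture_rel_std: float = 0.015,
    base_reflectance_range: tuple[float, float] = (0.75, 0.9),
    center_jitter: float = 4.0,
    axis_jitter: float = 5.0,
    bruise_center: tuple[float, float] | None = None,
    bruise_radius: float | None = None,
) -> PhantomScene:
    """Build a seeded fruit phantom for one bruise degree.

    Per-sample variability (fruit position/size, base reflectance, modulation
    texture, bruise placement and size) is drawn from ``seed``; the same seed
    and parameters always reproduce the same scene.  Bruise severity enters as
    an increasing AC-attenuation depth and radius (S1 < S2 < S3); S0 has an
    identically zero attenuation map.

    Raises
    ------
    GeometryError
        If an explicitly placed bruise does not fit inside the fruit ellipse.
    """
    if degree not in DEGREES:
        raise ValueError(f"unknown bruise degree {degree!r}; expected one of {DEGREES}")
    depths = dict(DEFAULT_BRUISE_DEPTHS, **(bruise_depths or {}))
    radii = dict(DEFAULT_BRUISE_RADII, **(bruise_radii or {}))
    rng = np.random.default_rng(seed)

    cr = height / 2.0 + rng.uniform(-center_jitter, center_jitter)
    cc = width / 2.0 + rng.uniform(-center_jitter, center_jitter)
    ar = 0.40 * height + rng.uniform(-axis_jitter, axis_jitter)
    ac = 0.34 * width + rng.uniform(-axis_jitter, axis_jitter)

    rr, col = np.mgrid[0:height, 0:width]
    rho = np.hypot((rr - cr) / ar, (col - cc) / ac)
    inside = rho <= 1.0
    base = rng.uniform(*base_reflectance_range)
    # per-sample curvature darkening; a pure illumination effect, so it
    # cancels exactly in the RT ratio but confounds DC/AC intensities
    strength = vignette_strength + rng.uniform(-vignette_jitter, vignette_jitter)
    vignette = 1.0 - strength * (1.0 - np.cos(0.5 * math.pi * np.clip(rho, 0, 1)))
    # per-sample linear illumination gradient (projector/sample geometry);
    # like the vignette it cancels in RT but shifts DC and AC intensities
    tilt = rng.uniform(0.0, illumination_tilt)
    phi = rng.uniform(0.0, TWO_PI)
    u = ((col - cc) / ac) * math.cos(phi) + ((rr - cr) / ar) * math.sin(phi)
    field = 1.0 - tilt * 0.5 * (1.0 + np.clip(u, -1.0, 1.0))
    reflectance = np.where(inside, base * vignette * field, 0.0)

    texture = rng.standard_normal((height, width))
    texture = ndimage.gaussian_filter(texture, sigma=8.0, mode="reflect")
    texture /= texture.std()
    texture = np.clip(1.0 + texture_rel_std * texture, 0.1, None)

    depth = float(depths[degree])
    radius = float(radii[degree] if bruise_radius is None else bruise_radius)
    if radius > 0:
        radius *= 1.0 if bruise_radius is not None else rng.uniform(0.9, 1.1)
    if degree == "S0":
        depth = 0.0
        radius = 0.0

    if bruise_center is None:
        # default placement: jitter around the fruit center, well inside the rim
        br = cr + rng.uniform(-0.3, 0.3) * ar
        bc = cc + rng.uniform(-0.3, 0.3) * ac
    else:
        br, bc = bruise_center
    if radius > 0:
        rho_b = math.hypot((br - cr) / ar, (bc - cc) / ac)
        if rho_b + radius / min(ar, ac) > 0.95:
            raise GeometryError(
                f"bruise (center=({br:.1f},{bc:.1f}), radius={radius:.1f}px) "
                "does not fit strictly inside the fruit ellipse"
            )
        dist = np.hypot(rr - br, col - bc)
        profile = _smoothstep((radius - dist) / (0.2 * radius)) * inside
    else:
        profile = np.zeros((height, width))

    return PhantomScene(
        width=width,
        height=height,
        pixel_pitch=pixel_pitch,
        fruit_center=(cr, cc),
        fruit_axes=(ar, ac),
        dc_reflectance_map=reflectance,
        modulation_texture=texture,
        mtf_scale=mtf_scale,
        bruise_center=(br, bc),
        bruise_radius=radius,
        bruise_degree=degree,
        bruise_depth=depth,
        bruise_peak_frequency=peak_frequency,
        bruise_profile=profile,
    )


def flat_field_scene(width: int = 64, height: int = 64, pixel_pitch: float = 5e-4) -> PhantomScene:
    """Idealized scene (reflectance = modulation = 1 everywhere, no bruise).

    Useful for demodulation exactness checks: rendered patterns are pure
    sinusoids of amplitude ``illum_ac`` on a pedestal ``illum_dc``.
    """
    ones = np.ones((height, width))
    return PhantomScene(
        width=width,
        height=height,
        pixel_pitch=pixel_pitch,
        fruit_center=(height / 2, width / 2),
        fruit_axes=(10 * height, 10 * width),
        dc_reflectance_map=ones,
        modulation_texture=ones.copy(),
        mtf_scale=math.inf,
        bruise_center=(height / 2, width / 2),
        bruise_radius=0.0,
        bruise_degree="S0",
        bruise_depth=0.0,
        bruise_peak_frequency=150.0,
        bruise_profile=np.zeros((height, width)),
    )


def render_triplet(
    scene: PhantomScene,
    illum: IlluminationSpec,
    noise: NoiseSpec = NoiseSpec(gaussian_sigma=0.0, quantize=False),
    *,
    sample_id: str = "sample",
) -> PatternTriplet:
    """Render the three phase-shifted pattern images of a scene.

    Per pixel and phase offset phi_n the intensity is

        R * I_DC + R * M(f) * (1 - c(f) * profile) * I_AC * cos(2*pi*f*x_m + phi_n)

    with R the diffuse reflectance, M(f) the per-pixel modulation transfer,
    c(f) the bruise attenuation depth and x_m the column coordinate in
    meters.  Gaussian noise is then added and, in 8-bit mode, values are
    clipped to [0, 255] and rounded.
    """
    illum.validate()
    f = illum.spatial_frequency
    x_m = np.arange(scene.width) * scene.pixel_pitch
    y_m = np.arange(scene.height) * scene.pixel_pitch
    carrier = (
        TWO_PI * f * x_m[None, :]
        + TWO_PI * illum.frequency_y * y_m[:, None]
        + illum.carrier_phase
    )
    amplitude = (
        scene.dc_reflectance_map
        * scene.modulation_map(f)
        * (1.0 - scene.bruise_attenuation_map(f))
        * illum.illum_ac
    )
    pedestal = scene.dc_reflectance_map * illum.illum_dc
    rng = np.random.default_rng(noise.rng_seed)
    images = []
    for phi in illum.phase_offsets:
        img = pedestal + amplitude * np.cos(carrier + phi)
        if noise.gaussian_sigma > 0:
            img = img + rng.normal(0.0, noise.gaussian_sigma, img.shape)
        if noise.quantize:
            img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
        images.append(img)
    return PatternTriplet(
        images=tuple(images),
        illumination=illum,
        sample_id=sample_id,
        degree=scene.bruise_degree,
    )


def to_uint8(image: np.ndarray) -> np.ndarray:
    if image.dtype == np.uint8:
        return image
    return np.clip(np.rint(image), 0, 255).astype(np.uint8)


def make_dataset(
    n_per_class: int,
    degrees: Sequence[str] = DEGREES,
    frequency: float = 150.0,
    noise: NoiseSpec = NoiseSpec(),
    seed: int = 0,
    out_dir: str | Path | None = None,
    phantom_kwargs: dict | None = None,
    illum_kwargs: dict | None = None,
) -> tuple[list[PatternTriplet], pd.DataFrame]:
    """Generate a balanced labeled set of pattern triplets with a manifest.

    One phantom and one noise realization per sample, all seeds derived
    deterministically from ``seed``.  When ``out_dir`` is given the images are
    written as 8-bit grayscale PNG (``<sample>_<phase>.png``) together with a
    ``manifest.csv`` (sample_id, degree, frequency_cpm, seed, file1..file3).
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    for d in degrees:
        if d not in DEGREES:
            raise ValueError(f"unknown bruise degree {d!r}")
    phantom_kwargs = phantom_kwargs or {}
    illum = IlluminationSpec(spatial_frequency=frequency, **(illum_kwargs or {}))
    master = np.random.default_rng(seed)
    sample_seeds = master.integers(0, 2**31 - 1, size=(len(degrees) * n_per_class, 2))

    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)

    triplets: list[PatternTriplet] = []
    records = []
    idx = 0
    for degree in degrees:
        for i in range(n_per_class):
            scene_seed, noise_seed = (int(s) for s in sample_seeds[idx])
            idx += 1
            sid = f"{degree}_{i:03d}"
            scene = make_phantom(degree, seed=scene_seed, **phantom_kwargs)
            trip = render_triplet(
                scene,
                illum,
                replace(noise, rng_seed=noise_seed),
                sample_id=sid,
            )
            triplets.append(trip)
            files = ["", "", ""]
            if out_path is not None:
                for p, img in enumerate(trip.images, start=1):
                    fname = f"{sid}_{p}.png"
                    iio.imwrite(out_path / fname, to_uint8(img))
                    files[p - 1] = fname
            records.append(
                {
                    "sample_id": sid,
                    "degree": degree,
                    "frequency_cpm": frequency,
                    "seed": scene_seed,
                    "file1": files[0],
                    "file2": files[1],
                    "file3": files[2],
                }
            )
    manifest = pd.DataFrame.from_records(records)
    if out_path is not None:
        manifest.to_csv(out_path / "manifest.csv", index=False)
    return triplets, manifest


def load_dataset(manifest_path: str | Path) -> tuple[list[PatternTriplet], pd.DataFrame]:
    """Read a rendered dataset back from its manifest CSV."""
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    manifest = pd.read_csv(manifest_path, keep_default_na=False)
    triplets = []
    for _, row in manifest.iterrows():
        imgs = tuple(
            np.asarray(iio.imread(root / row[f"file{p}"])) for p in (1, 2, 3)
        )
        triplets.append(
            PatternTriplet(
                images=imgs,
                illumination=IlluminationSpec(spatial_frequency=float(row["frequency_cpm"])),
                sample_id=str(row["sample_id"]),
                degree=str(row["degree"]),
            )
        )
    return triplets, manifest
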