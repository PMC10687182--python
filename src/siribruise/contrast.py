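"""Contrast index (CI) and spatial-frequency optimization.

The CI of a bruise/sound partition is the ratio of the between-class
variance to the total variance of the pixel intensities over the whole
fruit region:

    CI = [N_x*(xbar - zbar)^2 + N_y*(ybar - zbar)^2] / sum_i (z_i - zbar)^2

with x the bruise pixels, y the sound pixels and z their union.  CI lies
in [0, 1]; higher means the bruise is more distinguishable.  Sweeping the
illumination spatial frequency traces a rise-then-fall CI curve (depth of
interrogation shrinks with frequency while the modulated signal
attenuates), and the operating frequency is chosen where the mildest —
hardest to detect — bruises peak.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import demodulate, segment
from .synthetic_scene import IlluminationSpec, NoiseSpec, make_phantom, render_triplet

__all__ = [
    "ContrastResult",
    "FrequencySweep",
    "contrast_index",
    "frequency_sweep",
    "select_frequency",
]


@dataclass(frozen=True)
class ContrastResult:
    ci: float
    bruise_mean: float
    sound_mean: float
    whole_mean: float
    n_bruise: int
    n_sound: int
    n_whole: int


@dataclass
class FrequencySweep:
    """CI table (degrees x frequencies) plus the selected operating frequency."""

    frequencies: list[float]
    degrees: list[str]
    ci_table: pd.DataFrame  # index: degree, columns: frequency
    selected_frequency: float | None = None


def contrast_index(image: np.ndarray, seg: segment.RegionSegmentation) -> ContrastResult:
    """Between-class over total variance of the bruise/sound partition."""
    image = np.asarray(image, dtype=np.float64)
    x = image[seg.bruise_mask]
    y = image[seg.sound_mask]
    if x.size == 0 or y.size == 0:
        raise ValueError("both bruise and sound regions must be nonempty")
    z = image[seg.fruit_mask]
    xbar, ybar, zbar = x.mean(), y.mean(), z.mean()
    numerator = x.size * (xbar - zbar) ** 2 + y.size * (ybar - zbar) ** 2
    denominator = float(((z - zbar) ** 2).sum())
    if denominator == 0.0:
        ci = 0.0
    else:
        ci = numerator / denominator
    # two-class between-class variance can never exceed the total variance
    assert ci <= 1.0 + 1e-9, f"CI {ci} > 1 violates the variance decomposition"
    return ContrastResult(
        ci=float(min(ci, 1.0)),
        bruise_mean=float(xbar),
        sound_mean=float(ybar),
        whole_mean=float(zbar),
        n_bruise=x.size,
        n_sound=y.size,
        n_whole=z.size,
    )


def _ci_one_cell(
    degree: str,
    frequency: float,
    scene_seed: int,
    noise: NoiseSpec,
    noise_seed: int,
    phantom_kwargs: dict,
    filter_sigma: float,
    mask_threshold: float | None,
    source: str,
) -> float:
    scene = make_phantom(degree, seed=scene_seed, **phantom_kwargs)
    trip = render_triplet(
        scene,
        IlluminationSpec(spatial_frequency=frequency),
        NoiseSpec(noise.gaussian_sigma, noise.quantize, noise_seed),
    )
    dc, _ = demodulate.tpd_demodulate(trip)
    fruit = segment.fruit_mask_from_dc(dc, threshold=mask_threshold)
    demod = demodulate.demodulate_triplet(trip, filter_sigma=filter_sigma, mask=fruit)
    image = demod.rt_image if source == "RT" else demod.ac_image
    seg = segment.split_bruise_sound(image, fruit)
    return contrast_index(image, seg).ci


def frequency_sweep(
    frequencies,
    degrees=("S1", "S2", "S3"),
    replicates: int = 3,
    noise: NoiseSpec = NoiseSpec(gaussian_sigma=0.0, quantize=False),
    seed: int = 0,
    phantom_kwargs: dict | None = None,
    filter_sigma: float = 2.0,
    mask_threshold: float | None = None,
    source: str = "RT",
    rule: str = "mild-first",
) -> FrequencySweep:
    """Render -> demodulate -> segment -> CI over a (degree, frequency) grid.

    For each cell the CI is averaged over ``replicates`` independently
    seeded phantoms re-imaged at every frequency (the same phantoms are
    reused across frequencies so the sweep varies illumination only).  CI
    is computed on RT images by default — mild bruises are hard to segment
    in AC images.  Cells whose pipeline fails are recorded as missing and
    their frequencies excluded from selection.
    """
    frequencies = [float(f) for f in frequencies]
    degrees = list(degrees)
    if len(frequencies) < 1:
        raise ValueError("at least one frequency is required")
    phantom_kwargs = phantom_kwargs or {}
    master = np.random.default_rng(seed)
    seeds = master.integers(0, 2**31 - 1, size=(len(degrees), replicates, 2))

    table = pd.DataFrame(index=degrees, columns=frequencies, dtype=float)
    for i, degree in enumerate(degrees):
        for f in frequencies:
            cis = []
            for r in range(replicates):
                try:
                    cis.append(
                        _ci_one_cell(
                            degree,
                            f,
                            int(seeds[i, r, 0]),
                            noise,
                            int(seeds[i, r, 1]),
                            phantom_kwargs,
                            filter_sigma,
                            mask_threshold,
                            source,
                        )
                    )
                except (ValueError, AssertionError):
                    continue
            table.loc[degree, f] = float(np.mean(cis)) if cis else np.nan
    sweep = FrequencySweep(frequencies=frequencies, degrees=degrees, ci_table=table)
    sweep.selected_frequency = select_frequency(sweep, rule=rule)
    return sweep


def select_frequency(sweep: FrequencySweep, rule: str = "mild-first") -> float:
    """Pick the operating frequency from a completed CI table.

    ``mild-first``: maximize CI for the mildest degree (first row); break
    ties by CI of the next degree, and finally prefer the lower frequency.
    Frequencies with any missing cell are excluded.
    """
    if rule != "mild-first":
        raise ValueError(f"unknown selection rule {rule!r}")
    table = sweep.ci_table
    if table.empty:
        raise ValueError("empty CI table")
    complete = [f for f in sweep.frequencies if not table[f].isna().any()]
    if not complete:
        raise ValueError("no frequency has a complete CI column")
    # lexicographic: (CI mildest desc, CI next desc, ..., frequency asc)
    def key(f):
        return tuple(-table.loc[d, f] for d in sweep.degrees) + (f,)

    return float(min(complete, key=key))
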