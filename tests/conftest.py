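import numpy as np
import pytest

from siribruise.synthetic_scene import (
    IlluminationSpec,
    NoiseSpec,
    flat_field_scene,
    make_phantom,
    render_triplet,
)

NOISELESS = NoiseSpec(gaussian_sigma=0.0, quantize=False)


@pytest.fixture(scope="session")
def flat_triplet():
    """Noiseless unquantized flat-field triplet at 150 cycles/m."""
    scene = flat_field_scene(64, 64)
    return render_triplet(scene, IlluminationSpec(150.0), NOISELESS)


@pytest.fixture(scope="session")
def bruised_demod():
    """Noisy S2 phantom taken through demodulation with a fruit mask."""
    from siribruise import demodulate, segment

    scene = make_phantom("S2", seed=11)
    trip = render_triplet(scene, IlluminationSpec(150.0), NoiseSpec(1.0, True, 12))
    dc, _ = demodulate.tpd_demodulate(trip)
    fruit = segment.fruit_mask_from_dc(dc)
    demod = demodulate.demodulate_triplet(trip, mask=fruit)
    return scene, demod, fruit


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
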