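import numpy as np
import pytest

import ledscan as ls
from ledscan.synthetic import LeddSpec, ParticleSpec, SceneSpec


@pytest.fixture(scope="session")
def default_scene():
    """One full-size section with the default placement and noise model."""
    return ls.generate_micrograph(SceneSpec(seed=3))


@pytest.fixture(scope="session")
def clean_bead_scene():
    """20 non-touching beads (10 per class), no noise, no blur, 1 nm/px."""
    spec = SceneSpec(
        image_shape=(512, 512),
        seed=5,
        particles=ParticleSpec(
            n_6nm=10, n_10nm=10, placement="uniform",
            cluster_size_probs=(1.0, 0, 0, 0, 0), diameter_jitter=0.0,
        ),
        ledd=LeddSpec(count=1, radius_nm=(120, 160), margin_nm=200),
        noise_sigma=0.0,
        blur_sigma_nm=0.0,
    )
    return ls.generate_micrograph(spec)


@pytest.fixture(scope="session")
def texture_only_scene():
    """Pure two-phase chromatin + one LEDD, no beads, no noise, no blur."""
    spec = SceneSpec(
        image_shape=(768, 768),
        seed=8,
        particles=ParticleSpec(n_6nm=0, n_10nm=0),
        ledd=LeddSpec(count=1, radius_nm=(200, 250), margin_nm=300),
        noise_sigma=0.0,
        blur_sigma_nm=0.0,
    )
    return ls.generate_micrograph(spec)


def square_ledd_region(shape, r0, c0, side, scale=1.0):
    """Hand-built square LEDDRegion for geometry tests."""
    mask = np.zeros(shape, dtype=bool)
    mask[r0:r0 + side, c0:c0 + side] = True
    boundary = np.array([
        [r0 - 0.5, c0 - 0.5], [r0 - 0.5, c0 + side - 0.5],
        [r0 + side - 0.5, c0 + side - 0.5], [r0 + side - 0.5, c0 - 0.5],
        [r0 - 0.5, c0 - 0.5],
    ])
    return ls.LEDDRegion(
        id=0, boundary=boundary, area_um2=side * side * scale**2 * 1e-6,
        centroid_nm=((c0 + side / 2) * scale, (r0 + side / 2) * scale), mask=mask,
    )
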