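import numpy as np
import pytest

from fetomosaic import generate_texture


@pytest.fixture(scope="session")
def texture256():
    """Default placental texture at the working resolution."""
    return generate_texture(256, 256, rng=np.random.default_rng(0))


@pytest.fixture(scope="session")
def texture_large():
    """Texture large enough for orbiting trajectories."""
    return generate_texture(768, 768, rng=np.random.default_rng(5))


def random_near_affine(rng, max_rot_deg=10.0, max_trans=20.0, max_scale=0.2,
                       max_shear=0.05, max_proj=1e-3):
    """Seeded random near-affine homography (test helper)."""
    from fetomosaic import rigid_matrix

    h = rigid_matrix(rng.uniform(-max_rot_deg, max_rot_deg),
                     rng.uniform(-max_trans, max_trans),
                     rng.uniform(-max_trans, max_trans), degrees=True)
    h[0, 0] *= 1 + rng.uniform(-max_scale, max_scale)
    h[1, 1] *= 1 + rng.uniform(-max_scale, max_scale)
    h[0, 1] += rng.uniform(-max_shear, max_shear)
    h[1, 0] += rng.uniform(-max_shear, max_shear)
    h[2, 0] = rng.uniform(-max_proj, max_proj)
    h[2, 1] = rng.uniform(-max_proj, max_proj)
    return h
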