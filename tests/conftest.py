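import numpy as np
import pytest

import killscope as ks


@pytest.fixture
def clean_config():
    """Factory for small, noise-free, attacker-free scene configs.

    Well-separated slow cells on a clean background: segmentation and
    tracking should be exact, so these scenes anchor the deterministic
    geometry/tracking tests.
    """

    def make(**kw):
        base = dict(
            seed=7,
            n_tumor_cells=8,
            image_height_px=400,
            image_width_px=400,
            n_frames=8,
            noise_sd_nm=0.0,
            attacker_ratio=0.0,
            motility_sigma_um=(0.2, 0.0),
        )
        base.update(kw)
        return ks.SceneConfig(**base)

    return make


@pytest.fixture(scope="session")
def default_scene():
    """One default-condition scene (noise, attackers, kills), shared read-only."""
    cfg = ks.SceneConfig(seed=42)
    images, gt = ks.generate_scene(cfg)
    return cfg, images, gt
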