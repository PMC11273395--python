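"""Shared fixtures: tiny phantom datasets and small model configs.

Everything is generated programmatically and seeded; the tiny 32-px
configurations exercise every code path in seconds, while the desk-scale
(128-px) study runs live in the acceptance tests only.
"""

from __future__ import annotations

import numpy as np
import pytest

from octa_anomaly import bayes_unet, vqvae
from octa_anomaly.synthetic import PhantomConfig, make_dataset

TINY = PhantomConfig(image_size=32, n_seed_vessels=4, fov_margin=4,
                     vessel_width_range=(1.5, 2.5), rng_seed=0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory):
    """12 healthy + 4 diseased phantoms at 32 px, with masks + manifest."""
    out = tmp_path_factory.mktemp("tiny_data")
    manifest = make_dataset(12, 4, TINY, out)
    return manifest


@pytest.fixture(scope="session")
def tiny_vqvae_cfg():
    return vqvae.VqVaeConfig(image_size=32, channels=(8,), embedding_dim=16,
                             codebook_size=8, n_res_blocks=1, epochs=4,
                             batch_size=4, rng_seed=0)


@pytest.fixture(scope="session")
def tiny_unet_cfg():
    return bayes_unet.UnetConfig(depth=3, base_channels=8, epochs=2,
                                 crop_size=None, rng_seed=0)


@pytest.fixture(scope="session")
def tiny_vqvae(tiny_dataset, tiny_vqvae_cfg):
    return vqvae.train_vqvae(tiny_dataset, tiny_vqvae_cfg)


@pytest.fixture(scope="session")
def tiny_unet(tiny_dataset, tiny_unet_cfg):
    return bayes_unet.train_unet(tiny_dataset, tiny_unet_cfg)
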