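import dataclasses

import numpy as np
import pytest

from estan.config import NetConfig, PhantomConfig, TrainConfig
from estan.phantom import generate_dataset


@pytest.fixture(scope="session")
def tiny_phantom_config():
    """64x64 phantom sized so the tumor fits the mammary band comfortably."""
    return PhantomConfig(height=64, width=64, tumor_axis_px=24,
                         speckle_smoothing_sigma=1.0)


@pytest.fixture(scope="session")
def small_phantom_samples(tiny_phantom_config):
    """Eight 64x64 phantoms with tumors of 16-30 px, as ImageSamples."""
    phs = generate_dataset(
        8, size_sampler=lambda rng: float(rng.uniform(16, 30)),
        base_config=tiny_phantom_config, seed=7)
    return [p.to_image_sample(f"p{i}") for i, p in enumerate(phs)]


@pytest.fixture(scope="session")
def tiny_net_config():
    """Channels //16: big enough to segment blobs, small enough for seconds."""
    return NetConfig().scaled(16)


def random_mask(rng, shape=(16, 16), p=0.3, nonempty=True):
    m = (rng.random(shape) < p).astype(np.uint8)
    if nonempty and not m.any():
        m[tuple(rng.integers(0, s) for s in shape)] = 1
    return m


def random_blob(rng, shape=(64, 64), n_seeds=3, radius=6):
    """A connected-ish blob: union of a few discs."""
    h, w = shape
    yy, xx = np.mgrid[:h, :w]
    m = np.zeros(shape, dtype=np.uint8)
    cy, cx = rng.integers(radius, h - radius), rng.integers(radius, w - radius)
    for _ in range(n_seeds):
        r = rng.integers(2, radius + 1)
        m |= ((yy - cy) ** 2 + (xx - cx) ** 2 <= r * r).astype(np.uint8)
        cy = int(np.clip(cy + rng.integers(-radius, radius + 1), r, h - r - 1))
        cx = int(np.clip(cx + rng.integers(-radius, radius + 1), r, w - r - 1))
    return m
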