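"""Shared fixtures: tone signals, random corpora, synthetic image specs.

The random decomposition corpora are session-scoped because full EMD of
long signals is the expensive part of the suite; several tests (and the
completeness / validity checks) share one set of decompositions.
"""

from __future__ import annotations

import numpy as np
import pytest

from emdimage import (
    LesionSpec,
    SiftConfig,
    SyntheticImageSpec,
    decompose,
    decompose_image,
    make_synthetic_image,
    make_tone_signal,
    ToneSpec,
)


def rel_rms(a, b) -> float:
    """Relative RMS error of a against reference b."""
    a, b = np.asarray(a, float).ravel(), np.asarray(b, float).ravel()
    return float(np.sqrt(np.mean((a - b) ** 2)) / np.sqrt(np.mean(b**2)))


def pearson(a, b) -> float:
    return float(np.corrcoef(np.ravel(a), np.ravel(b))[0, 1])


@pytest.fixture(scope="session")
def two_tone():
    """50 Hz + half-amplitude 5 Hz over 1 s at 2 kHz, with components."""
    spec = ToneSpec(components=((50.0, 1.0, 0.0), (5.0, 0.5, 0.0)))
    signal, (fast, slow) = make_tone_signal(spec)
    return signal, fast, slow


@pytest.fixture(scope="session")
def signal_corpus():
    """Seeded random-walk signals and their full decompositions.

    Lengths span short to image-scale (64*64*3 = 12288); random walks are
    smooth enough to carry several IMFs but irregular enough to exercise
    the stopping rules.
    """
    rng = np.random.default_rng(20240601)
    corpus = []
    for n in (256,) * 20 + (1024,) * 20 + (12288,) * 10:
        x = np.cumsum(rng.standard_normal(n))
        corpus.append((x, decompose(x)))
    return corpus


@pytest.fixture(scope="session")
def image_corpus():
    """Seeded random images (32x32 and 64x64) with their decompositions."""
    rng = np.random.default_rng(7)
    corpus = []
    for side in (32,) * 12 + (64,) * 8:
        img = rng.uniform(0, 255, (side, side, 3))
        corpus.append((img, decompose_image(img)))
    return corpus


@pytest.fixture(scope="session")
def confounded_fixture():
    """Background + texture + lesion image with ground-truth components."""
    spec = SyntheticImageSpec(
        height=32,
        width=32,
        background_amp=50.0,
        texture_amp=10.0,
        texture_period=12.0,
        lesion=LesionSpec(center=(16.0, 16.0), radius=5.0, amplitude=40.0),
        noise_sd=2.0,
        seed=3,
    )
    image, comps = make_synthetic_image(spec)
    return image, comps, decompose_image(image)


@pytest.fixture
def sift_config():
    return SiftConfig()
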