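"""Synthetic fixtures with known ground truth.

Generators for (a) multi-tone 1D signals, (b) RGB images built from a slow
oscillation along the flattened scan order (standing in for background /
illumination drift), a fast scan-order texture tone, and a Gaussian-blob
"lesion", (c) directory-per-class image datasets emulating an endoscopy
collection, and (d) label/prediction tables with controlled per-class hit
rates. Every generator is deterministic under a fixed seed and returns its
ground-truth components alongside the composite, so decomposition and
enhancement behaviour can be checked against construction rather than by
eye.

The backgrounds oscillate along the *flattened* scan order, not as 2D
planes: the quasi-2D EMD operates on the flattened signal, so separability
must be posed in that space for the fixtures to exercise it.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .enhance import apply_output_policy, reshape_to_image, save_image

__all__ = [
    "ToneSpec",
    "SyntheticImageSpec",
    "LesionSpec",
    "make_tone_signal",
    "make_synthetic_image",
    "make_synthetic_dataset",
    "make_prediction_fixture",
]


@dataclass(frozen=True)
class ToneSpec:
    """A sum of sinusoids: components are (frequency_hz, amplitude, phase)."""

    components: tuple[tuple[float, float, float], ...]
    sample_rate: float = 2000.0
    duration: float = 1.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        freqs = [c[0] for c in self.components]
        if len(set(freqs)) != len(freqs):
            raise ValueError("component frequencies must be distinct")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def make_tone_signal(spec: ToneSpec) -> tuple[np.ndarray, list[np.ndarray]]:
    """Return (composite, per-component sequences); noise is the last
    component when ``noise_sd > 0``."""
    n = int(round(spec.sample_rate * spec.duration))
    t = np.arange(n) / spec.sample_rate
    parts = [amp * np.sin(2 * np.pi * f * t + ph) for f, amp, ph in spec.components]
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        parts.append(spec.noise_sd * rng.standard_normal(n))
    return np.sum(parts, axis=0), parts


@dataclass(frozen=True)
class LesionSpec:
    """Gaussian blob: centre (row, col), radius in pixels, peak amplitude,
    per-channel weights."""

    center: tuple[float, float]
    radius: float
    amplitude: float
    channel_weights: tuple[float, float, float] = (1.0, 1.0, 1.0)


@dataclass(frozen=True)
class SyntheticImageSpec:
    """An RGB image = base level + scan-order background + scan-order
    texture + optional lesion blob + optional Gaussian noise.

    ``background_period`` defaults to H*W*3 / 4 samples (at most four slow
    cycles over the whole scan, well below any texture frequency);
    ``texture_period`` must be fast (<= 30 samples) for the two to be
    separable by decomposition.
    """

    height: int = 32
    width: int = 32
    base_level: float = 128.0
    background_amp: float = 40.0
    background_period: float | None = None
    background_phase: float = 0.0
    texture_amp: float = 10.0
    texture_period: float = 12.0
    texture_phase: float = 0.0
    lesion: LesionSpec | None = None
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValueError("height and width must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def scan_length(self) -> int:
        return self.height * self.width * 3


def _lesion_image(spec: SyntheticImageSpec) -> np.ndarray:
    les = spec.lesion
    rows = np.arange(spec.height)[:, None]
    cols = np.arange(spec.width)[None, :]
    d2 = (rows - les.center[0]) ** 2 + (cols - les.center[1]) ** 2
    blob = les.amplitude * np.exp(-d2 / (2.0 * les.radius**2))
    return blob[:, :, None] * np.asarray(les.channel_weights)[None, None, :]


def make_synthetic_image(spec: SyntheticImageSpec) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Return (composite image, ground-truth component images).

    The composite is the exact elementwise sum of the components and is
    *not* clipped; clipping to [0, 255] happens only if the caller exports
    it. Component keys: base, background, texture, lesion, noise.
    """
    n = spec.scan_length
    t = np.arange(n, dtype=np.float64)
    bg_period = spec.background_period if spec.background_period is not None else n / 4.0
    background = spec.background_amp * np.sin(2 * np.pi * t / bg_period + spec.background_phase)
    texture = spec.texture_amp * np.sin(2 * np.pi * t / spec.texture_period + spec.texture_phase)
    comps = {
        "base": np.full((spec.height, spec.width, 3), spec.base_level),
        "background": reshape_to_image(background, spec.height, spec.width),
        "texture": reshape_to_image(texture, spec.height, spec.width),
    }
    if spec.lesion is not None:
        comps["lesion"] = _lesion_image(spec)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        comps["noise"] = spec.noise_sd * rng.standard_normal((spec.height, spec.width, 3))
    image = np.sum(list(comps.values()), axis=0)
    return image, comps


# Per-class texture periods (samples along the scan; all fast, <= 30) and
# lesion placements used by make_synthetic_dataset. Classes differ in
# texture frequency and in where/how strongly the blob appears.
_CLASS_TEXTURE_PERIODS = (6.0, 8.0, 10.0, 12.0, 15.0, 18.0, 24.0, 30.0)


def make_synthetic_dataset(
    out_dir,
    n_classes: int = 8,
    n_per_class: int = 5,
    confound_strength: float = 0.0,
    seed: int = 0,
    height: int = 32,
    width: int = 32,
    texture_amp: float = 12.0,
    lesion_amp: float = 40.0,
    noise_sd: float = 2.0,
    phase_jitter: float = np.pi / 2,
    confound_reliability: float = 0.75,
) -> list[dict]:
    """Write a directory-per-class PNG tree plus a ``truth.csv`` table.

    Classes differ by scan-order texture period (a fixed-phase fast tone,
    so the class signature is a stable pixel pattern) and by lesion
    placement / channel mix. A slow scan-order background of amplitude
    ``confound_strength`` is added to every image: with probability
    ``confound_reliability`` its phase is drawn around a class-dependent
    mean (2*pi*class/n_classes, jitter +/- ``phase_jitter``), otherwise
    uniformly — a *class-correlated but unreliable* low-frequency
    confound, emulating illumination drift that co-varies with class
    without being diagnostic. At strength 0 no background is added, so it
    is trivially independent of class.

    Returns the truth table (one dict per image, recording every generating
    parameter); deterministic per seed, including file checksums.
    """
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    if not 0.0 <= confound_reliability <= 1.0:
        raise ValueError("confound_reliability must lie in [0, 1]")
    out_dir = Path(out_dir)
    rng = np.random.default_rng(seed)
    truth: list[dict] = []
    for cls in range(n_classes):
        cdir = out_dir / f"class_{cls}"
        cdir.mkdir(parents=True, exist_ok=True)
        texture_period = _CLASS_TEXTURE_PERIODS[cls % len(_CLASS_TEXTURE_PERIODS)]
        for i in range(n_per_class):
            if confound_strength > 0:
                # consume the RNG identically on both branches so the rest
                # of the stream (and thus the images) stays comparable
                aligned = rng.random() < confound_reliability
                class_phase = 2 * np.pi * cls / n_classes + rng.uniform(-phase_jitter, phase_jitter)
                uniform_phase = rng.uniform(0, 2 * np.pi)
                bg_phase = float(class_phase if aligned else uniform_phase)
            else:
                bg_phase = 0.0
            lesion = LesionSpec(
                center=(
                    height * (0.25 + 0.5 * ((cls % 4) // 2)),
                    width * (0.25 + 0.5 * (cls % 2)),
                ),
                radius=min(height, width) / 6.0,
                amplitude=lesion_amp,
                channel_weights=(
                    (1.0, 0.3, 0.3) if cls % 3 == 0 else
                    (0.3, 1.0, 0.3) if cls % 3 == 1 else (0.3, 0.3, 1.0)
                ),
            )
            spec = SyntheticImageSpec(
                height=height,
                width=width,
                background_amp=float(confound_strength),
                background_phase=bg_phase,
                texture_amp=texture_amp,
                texture_period=texture_period,
                texture_phase=0.0,
                lesion=lesion,
                noise_sd=noise_sd,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            image, _ = make_synthetic_image(spec)
            fname = f"img_{i:04d}.png"
            save_image(cdir / fname, apply_output_policy(image, "float"), "clip_8bit")
            truth.append(
                {
                    "path": f"class_{cls}/{fname}",
                    "label": cls,
                    "texture_period": texture_period,
                    "texture_phase": spec.texture_phase,
                    "background_amp": spec.background_amp,
                    "background_phase": bg_phase,
                    "lesion_row": lesion.center[0],
                    "lesion_col": lesion.center[1],
                    "noise_seed": spec.seed,
                }
            )
    with open(out_dir / "truth.csv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(truth[0].keys()))
        writer.writeheader()
        writer.writerows(truth)
    return truth


def make_prediction_fixture(
    tpr_targets,
    n: int,
    seed: int = 0,
    class_probs=None,
    error_routing=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (true labels, predicted labels) with target per-class hit rates.

    For a sample of class c the prediction is correct with probability
    ``tpr_targets[c]``; otherwise the wrong label is drawn from
    ``error_routing[c]`` (a distribution over classes, self-mass ignored;
    uniform over the other classes by default). Per-class false-positive
    rates follow from the routed error mass and the class marginals
    ``class_probs`` (uniform by default). Empirical rates concentrate
    around the targets at binomial speed; deterministic per seed.
    """
    tpr = np.asarray(tpr_targets, dtype=np.float64)
    if np.any(tpr < 0) or np.any(tpr > 1):
        raise ValueError("TPR targets must lie in [0, 1]")
    k = len(tpr)
    probs = np.full(k, 1.0 / k) if class_probs is None else np.asarray(class_probs, float)
    rng = np.random.default_rng(seed)
    y_true = rng.choice(k, size=n, p=probs / probs.sum())
    y_pred = y_true.copy()
    wrong = rng.random(n) >= tpr[y_true]
    for c in range(k):
        mask = wrong & (y_true == c)
        m = int(mask.sum())
        if m == 0:
            continue
        if error_routing is not None:
            w = np.asarray(error_routing[c], dtype=np.float64).copy()
        else:
            w = np.ones(k)
        w[c] = 0.0
        if w.sum() == 0:
            raise ValueError(f"error routing for class {c} has no mass off the diagonal")
        y_pred[mask] = rng.choice(k, size=m, p=w / w.sum())
    return y_true, y_pred
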