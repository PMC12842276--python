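"""Dataset preparation for directory-per-class endoscopy image collections.

Covers the preprocessing pipeline used ahead of classifier training:
enumerating a Kvasir-style directory tree into (path, label) pairs with a
fixed 8-class label map, automated black-border cropping, 64x64 bilinear
resizing, and the stratified 60/40 train+val/test split followed by a
70/30 train/val split of the first part. For the canonical 8 x 1000 image
layout this yields 3360 / 1440 / 3200 train / val / test images.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.transform import resize as _sk_resize

from .enhance import load_image, save_image

__all__ = [
    "KVASIR_CLASSES",
    "LabeledImageSet",
    "DatasetSplit",
    "load_labeled_set",
    "crop_black_border",
    "resize_image",
    "split_dataset",
    "export_split",
    "load_split",
    "prepare_images",
]

# Fixed label order: Polyps=0 ... Normal-Z-Line=7.
KVASIR_CLASSES = (
    "polyps",
    "dyed-resection-margins",
    "normal-pylorus",
    "normal-cecum",
    "esophagitis",
    "dyed-lifted-polyps",
    "ulcerative-colitis",
    "normal-z-line",
)

_IMAGE_SUFFIXES = {".png", ".jpg", ".jpeg"}


@dataclass(frozen=True)
class LabeledImageSet:
    """(path, label) pairs with the ordered class-name -> label map."""

    items: tuple[tuple[Path, int], ...]
    class_names: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.items)

    @property
    def labels(self) -> np.ndarray:
        return np.array([lab for _, lab in self.items], dtype=np.intp)

    @property
    def paths(self) -> list[Path]:
        return [p for p, _ in self.items]


@dataclass(frozen=True)
class DatasetSplit:
    """Disjoint stratified train/val/test index partition."""

    train_indices: np.ndarray
    val_indices: np.ndarray
    test_indices: np.ndarray
    seed: int
    test_fraction: float = 0.4
    val_fraction: float = 0.3  # of the non-test remainder

    def __post_init__(self) -> None:
        parts = (self.train_indices, self.val_indices, self.test_indices)
        concat = np.concatenate(parts)
        if len(np.unique(concat)) != len(concat):
            raise ValueError("split partitions overlap")

    @property
    def n(self) -> int:
        return len(self.train_indices) + len(self.val_indices) + len(self.test_indices)


def load_labeled_set(root, class_names=None) -> LabeledImageSet:
    """Enumerate a directory-per-class tree deterministically.

    Expects one subdirectory per class named after ``class_names``
    (the 8-class endoscopy map by default; matching is case-insensitive).
    Enumeration is lexicographic within each class, so the result does not
    depend on on-disk ordering. Missing class directories raise; unknown
    extra directories raise too, listing the expected names; empty class
    directories warn.
    """
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(f"dataset root {root} is not a directory")
    names = tuple(class_names) if class_names is not None else KVASIR_CLASSES
    lookup = {n.lower(): i for i, n in enumerate(names)}
    found = {p.name.lower(): p for p in root.iterdir() if p.is_dir()}
    missing = sorted(set(lookup) - set(found))
    if missing:
        raise FileNotFoundError(f"missing class directories: {missing}; expected {sorted(lookup)}")
    unknown = sorted(set(found) - set(lookup))
    if unknown:
        raise ValueError(f"unknown class directories: {unknown}; expected {sorted(lookup)}")
    items: list[tuple[Path, int]] = []
    for name in sorted(lookup, key=lookup.get):
        cdir = found[name]
        files = sorted(f for f in cdir.iterdir() if f.suffix.lower() in _IMAGE_SUFFIXES)
        if not files:
            warnings.warn(f"class directory {cdir} contains no images", stacklevel=2)
        items.extend((f, lookup[name]) for f in files)
    return LabeledImageSet(items=tuple(items), class_names=names)


def crop_black_border(image, luminance_threshold: float = 10 / 255) -> np.ndarray:
    """Strip dark frame rows/columns from the image edges.

    Removes the maximal contiguous runs of edge rows and columns whose mean
    luminance is below ``luminance_threshold`` (on a 0-1 scale; pixels are
    0-255). An all-dark image is returned unchanged rather than empty.
    """
    img = np.asarray(image, dtype=np.float64)
    lum = img.mean(axis=2) / 255.0
    rows = lum.mean(axis=1) >= luminance_threshold
    cols = lum.mean(axis=0) >= luminance_threshold
    if not rows.any() or not cols.any():
        return img
    r0, r1 = np.flatnonzero(rows)[[0, -1]]
    c0, c1 = np.flatnonzero(cols)[[0, -1]]
    return img[r0 : r1 + 1, c0 : c1 + 1]


def resize_image(image, size: tuple[int, int] = (64, 64)) -> np.ndarray:
    """Bilinear, anti-aliased resize to ``size`` (float64, 0-255 scale)."""
    img = np.asarray(image, dtype=np.float64)
    return _sk_resize(
        img, (*size, 3), order=1, anti_aliasing=True, preserve_range=True
    ).astype(np.float64)


def split_dataset(
    labeled_set: LabeledImageSet | np.ndarray,
    seed: int = 0,
    test_fraction: float = 0.4,
    val_fraction: float = 0.3,
) -> DatasetSplit:
    """Stratified two-stage split: test off the top, then val off the rest.

    Per class, ``floor(test_fraction * n_c)`` items go to test and
    ``floor(val_fraction * remainder)`` to validation; rounding remainders
    stay in train. Shuffling within each class uses ``seed``, so the same
    seed always reproduces the same partition. Accepts either a
    :class:`LabeledImageSet` or a bare label array.
    """
    labels = labeled_set.labels if isinstance(labeled_set, LabeledImageSet) else np.asarray(labeled_set)
    rng = np.random.default_rng(seed)
    train, val, test = [], [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < 2:
            raise ValueError(f"class {cls} has fewer than 2 items; cannot stratify")
        idx = rng.permutation(idx)
        n_test = int(np.floor(test_fraction * len(idx)))
        n_val = int(np.floor(val_fraction * (len(idx) - n_test)))
        test.append(idx[:n_test])
        val.append(idx[n_test : n_test + n_val])
        train.append(idx[n_test + n_val :])
    return DatasetSplit(
        train_indices=np.sort(np.concatenate(train)),
        val_indices=np.sort(np.concatenate(val)),
        test_indices=np.sort(np.concatenate(test)),
        seed=seed,
        test_fraction=test_fraction,
        val_fraction=val_fraction,
    )


def export_split(split: DatasetSplit, labeled_set: LabeledImageSet, path) -> Path:
    """Write a (path, label, partition) CSV manifest of the split."""
    rows = []
    for part, indices in (
        ("train", split.train_indices),
        ("val", split.val_indices),
        ("test", split.test_indices),
    ):
        for i in indices:
            p, lab = labeled_set.items[i]
            rows.append({"index": int(i), "path": str(p), "label": int(lab), "partition": part})
    df = pd.DataFrame(rows).sort_values("index")
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def load_split(path, seed: int = 0) -> tuple[DatasetSplit, pd.DataFrame]:
    """Read an exported split manifest back into a :class:`DatasetSplit`."""
    df = pd.read_csv(path)
    parts = {
        part: np.sort(df.loc[df["partition"] == part, "index"].to_numpy(dtype=np.intp))
        for part in ("train", "val", "test")
    }
    split = DatasetSplit(
        train_indices=parts["train"],
        val_indices=parts["val"],
        test_indices=parts["test"],
        seed=seed,
    )
    return split, df


def prepare_images(
    root,
    out_dir,
    crop: bool = True,
    size: tuple[int, int] | None = (64, 64),
    class_names=None,
) -> list[Path]:
    """Crop/resize every image in a class tree into a mirrored tree."""
    ls = load_labeled_set(root, class_names=class_names)
    root, out_dir = Path(root), Path(out_dir)
    written = []
    for path, _ in ls.items:
        img = load_image(path)
        if crop:
            img = crop_black_border(img)
        if size is not None:
            img = resize_image(img, size)
        rel = path.relative_to(root)
        target = (out_dir / rel).with_suffix(".png")
        target.parent.mkdir(parents=True, exist_ok=True)
        written.append(save_image(target, img, "clip_8bit"))
    return written
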