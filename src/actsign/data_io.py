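"""Dataset handling: class-folder images, splits, and synthetic phantoms.

Real data is read from the common ``<root>/<class_name>/*.jpg`` layout
(as used by the public four-class brain-MRI collection with classes
glioma / meningioma / notumor / pituitary).  For development and
testing, :func:`generate_phantoms` produces a synthetic four-class set
in the same in-memory form: an elliptical "brain" on a dark field, with
class-specific lesions —

* ``glioma``     an irregular multi-lobed blob in the brain interior,
* ``meningioma`` a bright blob attached to the brain rim,
* ``notumor``    background anatomy only,
* ``pituitary``  a small midline blob low in the brain,

plus per-pixel Gaussian noise.  The classes are visually separable by
construction, so a classifier that learns anything at all should
separate them; that is what end-to-end training tests rely on.

Splitting follows the conventional 70/10/20 train/validation/test
fractions, stratified per class, seeded and deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError

logger = logging.getLogger(__name__)

__all__ = [
    "LabeledImageSet",
    "SplitSpec",
    "PhantomSpec",
    "PHANTOM_CLASS_NAMES",
    "load_image_folder",
    "split_dataset",
    "split_indices",
    "generate_phantoms",
    "save_image_folder",
    "DATASET_COMPOSITION",
    "DATASET_PRINTED_CLASS_TOTALS",
    "DATASET_PRINTED_TOTAL",
    "dataset_class_totals",
    "dataset_total",
]

PHANTOM_CLASS_NAMES = ["glioma", "meningioma", "notumor", "pituitary"]


class DatasetError(ValueError):
    """Problem with an on-disk dataset or a split specification."""


@dataclass
class LabeledImageSet:
    """Images as an (N, H, W, C) float array in [0, 1] with int labels."""

    images: np.ndarray
    labels: np.ndarray
    class_names: list[str]
    provenance: str = "folder"  # "folder" or "phantom"

    def __post_init__(self):
        self.images = np.asarray(self.images, np.float32)
        self.labels = np.asarray(self.labels, np.int64)
        if len(self.images) != len(self.labels):
            raise DatasetError("images and labels length mismatch")
        if len(self.labels) and self.labels.max() >= len(self.class_names):
            raise DatasetError("label out of range of class_names")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def num_classes(self) -> int:
        return len(self.class_names)

    def subset(self, indices: np.ndarray) -> "LabeledImageSet":
        return LabeledImageSet(self.images[indices], self.labels[indices],
                               self.class_names, self.provenance)

    def class_counts(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.num_classes)


@dataclass(frozen=True)
class SplitSpec:
    """Train/validation/test fractions; stratified and seeded by default."""

    train: float = 0.7
    val: float = 0.1
    test: float = 0.2
    seed: int = 0
    stratified: bool = True

    def __post_init__(self):
        for f in (self.train, self.val, self.test):
            if not (0.0 < f < 1.0):
                raise DatasetError(f"split fraction {f} not in (0, 1)")
        if abs(self.train + self.val + self.test - 1.0) > 1e-9:
            raise DatasetError(
                f"split fractions sum to {self.train + self.val + self.test}, expected 1")


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic phantom generator.

    ``noise_sd`` is the standard deviation of additive Gaussian pixel
    noise (image values live in [0, 1]); lesion geometry is controlled
    by the radius ranges and the positional jitter, all in units of the
    image side length.
    """

    n_per_class: int = 100
    image_size: tuple[int, int] = (224, 224)
    noise_sd: float = 0.05
    seed: int = 0
    blob_radius: tuple[float, float] = (0.06, 0.11)
    rim_radius: tuple[float, float] = (0.05, 0.09)
    small_radius: tuple[float, float] = (0.03, 0.05)
    jitter: float = 0.08

    def __post_init__(self):
        if self.n_per_class < 1:
            raise DatasetError("n_per_class must be >= 1")
        if not (0.0 <= self.noise_sd < 0.5):
            raise DatasetError("noise_sd must be in [0, 0.5)")


def load_image_folder(root, target_size: tuple[int, int] = (224, 224)) -> LabeledImageSet:
    """Read a ``<root>/<class_name>/*`` tree into a labeled image set.

    Every decodable image is converted to RGB, resized to
    ``target_size`` with bilinear interpolation, and scaled to [0, 1].
    Class indices follow the alphabetically sorted folder names.
    Undecodable files are skipped with a warning; an empty class folder
    is an error.
    """
    root = Path(root)
    class_dirs = sorted(d for d in root.iterdir() if d.is_dir())
    if not class_dirs:
        raise DatasetError(f"no class subdirectories under {root}")
    class_names = [d.name for d in class_dirs]
    if len(class_names) != 4:
        logger.warning("expected 4 class folders, found %d: %s",
                       len(class_names), class_names)
    images, labels = [], []
    skipped = 0
    for k, d in enumerate(class_dirs):
        files = sorted(p for p in d.iterdir() if p.is_file())
        n_before = len(images)
        for p in files:
            try:
                with Image.open(p) as im:
                    im = im.convert("RGB").resize(
                        (target_size[1], target_size[0]), Image.BILINEAR)
                    images.append(np.asarray(im, np.float32) / 255.0)
                    labels.append(k)
            except (UnidentifiedImageError, OSError):
                skipped += 1
                logger.warning("skipping undecodable file %s", p)
        if len(images) == n_before:
            raise DatasetError(f"class folder {d} contains no decodable images")
    if skipped:
        logger.warning("skipped %d undecodable files in total", skipped)
    return LabeledImageSet(np.stack(images), np.array(labels), class_names, "folder")


def split_indices(dataset: LabeledImageSet, spec: SplitSpec):
    """Index arrays of the (train, val, test) partition.

    Per class of size n the split takes floor(train·n) training images,
    then up to floor((train+val)·n) for validation, and the remainder
    for test — each within one image of the exact fractions.  The same
    seed always yields the same index assignment.
    """
    if len(dataset) == 0:
        raise DatasetError("cannot split an empty dataset")
    rng = np.random.Generator(np.random.PCG64(spec.seed))
    groups = ([np.flatnonzero(dataset.labels == k) for k in range(dataset.num_classes)]
              if spec.stratified else [np.arange(len(dataset))])
    tr, va, te = [], [], []
    for k, idx in enumerate(groups):
        if len(idx) < 3:
            name = dataset.class_names[k] if spec.stratified else "<all>"
            raise DatasetError(
                f"class {name!r} has only {len(idx)} images, fewer than the 3 splits")
        idx = rng.permutation(idx)
        n = len(idx)
        # 1e-9 guards the floor against float artifacts like 0.7+0.1 = 0.799…9
        n_tr = int(np.floor(spec.train * n + 1e-9))
        n_va = int(np.floor((spec.train + spec.val) * n + 1e-9)) - n_tr
        tr.append(idx[:n_tr])
        va.append(idx[n_tr:n_tr + n_va])
        te.append(idx[n_tr + n_va:])
    return tuple(np.sort(np.concatenate(part)) for part in (tr, va, te))


def split_dataset(dataset: LabeledImageSet, spec: SplitSpec):
    """Partition into (train, val, test) subsets; see :func:`split_indices`."""
    tr, va, te = split_indices(dataset, spec)
    return dataset.subset(tr), dataset.subset(va), dataset.subset(te)


# -- phantom generator ------------------------------------------------------

def _disc(yy, xx, cy, cx, r):
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r


def _phantom_image(rng: np.random.Generator, label: int, h: int, w: int,
                   spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """One grayscale phantom in [0,1] of shape (h, w) plus its lesion mask."""
    yy, xx = np.mgrid[0:h, 0:w]
    yy = yy / (h - 1)
    xx = xx / (w - 1)
    img = np.full((h, w), 0.02, np.float32)
    # elliptical brain: center (0.5, 0.5), semi-axes 0.42 (y) x 0.34 (x)
    brain = ((yy - 0.5) / 0.42) ** 2 + ((xx - 0.5) / 0.34) ** 2 <= 1.0
    img[brain] = 0.45
    # faint interior shading so "notumor" is not constant
    img += brain * 0.06 * np.cos(6.0 * np.pi * yy).astype(np.float32) * 0.5

    j = spec.jitter
    lesion = np.zeros((h, w), bool)
    if label == 0:  # glioma: irregular multi-lobed interior blob
        cy = 0.42 + rng.uniform(-j, j)
        cx = 0.45 + rng.uniform(-j, j)
        mask = np.zeros((h, w), bool)
        for _ in range(3):
            r = rng.uniform(*spec.blob_radius)
            dy, dx = rng.uniform(-0.05, 0.05, size=2)
            mask |= _disc(yy, xx, cy + dy, cx + dx, r)
        lesion = mask & brain
        img[lesion] = 0.80
    elif label == 1:  # meningioma: bright rim-attached peripheral blob
        theta = rng.uniform(0, 2 * np.pi)
        cy = 0.5 + 0.42 * np.sin(theta)
        cx = 0.5 + 0.34 * np.cos(theta)
        r = rng.uniform(*spec.rim_radius)
        lesion = _disc(yy, xx, cy, cx, r)
        img[lesion] = 0.95
    elif label == 3:  # pituitary: small midline-inferior blob
        cy = 0.72 + rng.uniform(-j / 2, j / 2)
        cx = 0.50 + rng.uniform(-j / 2, j / 2)
        r = rng.uniform(*spec.small_radius)
        lesion = _disc(yy, xx, cy, cx, r) & brain
        img[lesion] = 0.90
    # label == 2: notumor, background only
    return np.clip(img, 0.0, 1.0), lesion


def generate_phantoms(spec: PhantomSpec, return_masks: bool = False):
    """Generate a deterministic 4-class phantom dataset.

    The same ``spec`` (including seed) always regenerates the identical
    set bit for bit.  Images are grayscale replicated to 3 channels,
    with additive Gaussian noise of sd ``noise_sd`` clipped to [0, 1].
    With ``return_masks=True`` also returns the (N, H, W) boolean lesion
    masks (all-False for the notumor class) for localization checks.
    """
    h, w = spec.image_size
    rng = np.random.Generator(np.random.PCG64(spec.seed))
    n_total = 4 * spec.n_per_class
    images = np.empty((n_total, h, w, 3), np.float32)
    labels = np.empty(n_total, np.int64)
    masks = np.empty((n_total, h, w), bool) if return_masks else None
    i = 0
    for label in range(4):
        for _ in range(spec.n_per_class):
            base, lesion = _phantom_image(rng, label, h, w, spec)
            img = np.repeat(base[:, :, None], 3, axis=2)
            if spec.noise_sd > 0:
                img = img + rng.normal(0.0, spec.noise_sd, size=img.shape).astype(np.float32)
                img = np.clip(img, 0.0, 1.0)
            images[i] = img
            labels[i] = label
            if return_masks:
                masks[i] = lesion
            i += 1
    dataset = LabeledImageSet(images, labels, list(PHANTOM_CLASS_NAMES), "phantom")
    if return_masks:
        return dataset, masks
    return dataset


def save_image_folder(dataset: LabeledImageSet, root) -> None:
    """Materialize a labeled set as a ``<root>/<class>/*.png`` tree."""
    root = Path(root)
    for k, name in enumerate(dataset.class_names):
        (root / name).mkdir(parents=True, exist_ok=True)
    counters = [0] * dataset.num_classes
    for img, label in zip(dataset.images, dataset.labels):
        name = dataset.class_names[label]
        arr = np.clip(img * 255.0, 0, 255).astype(np.uint8)
        Image.fromarray(arr).save(root / name / f"{name}_{counters[label]:05d}.png")
        counters[label] += 1


# -- reference dataset bookkeeping ------------------------------------------

#: Per-source image counts of the public four-class brain-MRI collection
#: (an aggregation of the figshare, SARTAJ and Br35H sets).
DATASET_COMPOSITION = {
    "gliomas": {"figshare": 1426, "SARTAJ": 195},
    "meningiomas": {"figshare": 708, "SARTAJ": 937},
    "pituitaries": {"figshare": 930, "SARTAJ": 827},
    "normal": {"SARTAJ": 500, "Br35H": 1500},
}

#: Published per-class totals of that collection.
DATASET_PRINTED_CLASS_TOTALS = {
    "gliomas": 1621,
    "meningiomas": 1645,
    "pituitaries": 1757,
    "normal": 2000,
}

#: Published grand total.
DATASET_PRINTED_TOTAL = 7023


def dataset_class_totals() -> dict[str, int]:
    """Per-class totals recomputed from the per-source composition."""
    return {cls: sum(sources.values()) for cls, sources in DATASET_COMPOSITION.items()}


def dataset_total() -> int:
    """Grand total recomputed from the per-source composition."""
    return sum(dataset_class_totals().values())
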