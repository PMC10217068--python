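"""Dataset plumbing: class-per-folder image I/O, the two-stage 80/20 split,
9-fold training augmentation and a seeded synthetic fundus generator.

Split arithmetic
----------------
Per class, 20% of the images (rounded to the nearest integer) are held out
for testing; of the remainder, 20% (again rounded) go to validation and the
rest to training.  Rounding to nearest — rather than flooring — reproduces
the reference per-class counts for all four classes (e.g. 1038 -> 664 train
/ 166 validation / 208 test).  Because class sizes are integers, ``0.2 * n``
never lands exactly on .5, so no tie-break rule is needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image as PILImage
from scipy import ndimage

from .errors import InvalidArgumentError

__all__ = [
    "CLASSES",
    "LabeledImageSet",
    "DatasetSplit",
    "SyntheticConfig",
    "split_counts",
    "split_dataset",
    "augment_image",
    "generate_synthetic_dataset",
    "load_image_folder",
    "save_image_set",
]

#: Canonical class order used throughout the package.
CLASSES = ("cataract", "diabetic_retinopathy", "glaucoma", "normal")

#: Number of augmented variants produced per training image; the augmented
#: training set holds exactly this many images per original.
AUGMENTATION_FACTOR = 9

#: Published per-class image counts of the reference four-class dataset.
REFERENCE_CLASS_SIZES = {
    "cataract": 1038,
    "diabetic_retinopathy": 1098,
    "glaucoma": 1007,
    "normal": 1074,
}


@dataclass
class LabeledImageSet:
    """Images (arrays or paths) paired with class labels."""

    items: list  # list of (np.ndarray | Path, label)
    classes: tuple = CLASSES

    def __post_init__(self):
        if not self.items:
            raise InvalidArgumentError("empty image set")
        bad = {lab for _, lab in self.items if lab not in self.classes}
        if bad:
            raise InvalidArgumentError(f"unknown labels: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.items)

    @property
    def labels(self) -> list:
        return [lab for _, lab in self.items]

    def image(self, i: int) -> np.ndarray:
        obj, _ = self.items[i]
        if isinstance(obj, np.ndarray):
            return obj
        return np.asarray(PILImage.open(obj).convert("RGB"))

    def class_indices(self, label: str) -> list:
        return [i for i, (_, lab) in enumerate(self.items) if lab == label]


@dataclass(frozen=True)
class DatasetSplit:
    train: tuple
    validation: tuple
    test: tuple
    per_class: dict = field(default_factory=dict)  # label -> (n_train, n_val, n_test)

    def __post_init__(self):
        parts = (set(self.train), set(self.validation), set(self.test))
        total = sum(len(p) for p in parts)
        if len(parts[0] | parts[1] | parts[2]) != total:
            raise InvalidArgumentError("split partitions overlap")


def split_counts(n: int) -> tuple:
    """(train, validation, test) counts for a class of ``n`` images."""
    if n < 5:
        raise InvalidArgumentError(f"need at least 5 images per class, got {n}")
    test = round(0.2 * n)
    rest = n - test
    validation = round(0.2 * rest)
    train = rest - validation
    return train, validation, test


def split_dataset(image_set: LabeledImageSet, seed: int) -> DatasetSplit:
    """Two-stage per-class 80/20 split with seeded shuffling.

    Counts are deterministic functions of the class sizes; only membership
    depends on the seed.
    """
    rng = np.random.default_rng(seed)
    train, val, test = [], [], []
    per_class = {}
    for label in image_set.classes:
        idx = np.array(image_set.class_indices(label), dtype=int)
        if idx.size == 0:
            continue
        n_train, n_val, n_test = split_counts(idx.size)
        rng.shuffle(idx)
        test.extend(idx[:n_test].tolist())
        val.extend(idx[n_test : n_test + n_val].tolist())
        train.extend(idx[n_test + n_val :].tolist())
        per_class[label] = (n_train, n_val, n_test)
    return DatasetSplit(
        train=tuple(train), validation=tuple(val), test=tuple(test), per_class=per_class
    )


def _shift_edge(img: np.ndarray, dr: int, dc: int) -> np.ndarray:
    """Translate with edge replication (no wrap-around)."""
    out = img
    if dr:
        pad = ((dr, 0), (0, 0)) + (((0, 0),) if img.ndim == 3 else ())
        out = np.pad(out, pad, mode="edge")[: img.shape[0]]
    if dc:
        pad = ((0, 0), (dc, 0)) + (((0, 0),) if img.ndim == 3 else ())
        out = np.pad(out, pad, mode="edge")[:, : img.shape[1]]
    return out


def _rotate_small(img: np.ndarray, angle: float) -> np.ndarray:
    axes = (0, 1)
    out = ndimage.rotate(
        img.astype(float), angle, axes=axes, reshape=False, order=1, mode="nearest"
    )
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def augment_image(img: np.ndarray, seed: int = 0) -> list:
    """Exactly 9 deterministic variants of one image.

    Horizontal and vertical flips, rotations by 90/180/270 and +-15 degrees,
    and 10% shifts along each axis with replicated borders.  The seed is
    accepted for interface stability; all variants are deterministic.
    """
    img = np.asarray(img)
    if img.size == 0 or img.ndim not in (2, 3):
        raise InvalidArgumentError("invalid image")
    del seed
    h, w = img.shape[:2]
    variants = [
        img[:, ::-1].copy(),  # horizontal flip
        img[::-1, :].copy(),  # vertical flip
        np.rot90(img, 1).copy(),
        np.rot90(img, 2).copy(),
        np.rot90(img, 3).copy(),
        _rotate_small(img, 15.0),
        _rotate_small(img, -15.0),
        _shift_edge(img, 0, max(1, round(0.1 * w))),
        _shift_edge(img, max(1, round(0.1 * h)), 0),
    ]
    return variants


# ---------------------------------------------------------------------------
# synthetic fundus generator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the synthetic class-conditioned fundus generator.

    Setting an effect size to zero makes the corresponding disease class
    pixel-identical to the ``normal`` class at the same image index, because
    base-image randomness and effect randomness use separate seeded streams.
    """

    n_per_class: int = 100
    image_size: tuple = (64, 64)
    seed: int = 0
    haze_strength: float = 0.6  # cataract: global veil + blur
    lesion_count: int = 15  # diabetic_retinopathy: max blob count (0 disables)
    lesion_intensity: float = 1.0  # blob/speckle strength
    cup_to_disc: float = 1.0  # glaucoma: disc centring fraction + enlargement
    noise_sigma: float = 3.0

    def __post_init__(self):
        if self.n_per_class < 1:
            raise InvalidArgumentError("n_per_class must be positive")
        if min(self.image_size) < 16:
            raise InvalidArgumentError("image_size must be at least 16x16")


def _disc_mask(h: int, w: int, cy: float, cx: float, radius: float) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2


def _soft_blob(h: int, w: int, cy: float, cx: float, radius: float) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w]
    d2 = (yy - cy) ** 2 + (xx - cx) ** 2
    return np.exp(-d2 / (2.0 * radius**2))


def _synth_image(cfg: SyntheticConfig, label: str, index: int) -> np.ndarray:
    h, w = cfg.image_size
    class_idx = CLASSES.index(label)
    rng_base = np.random.default_rng([cfg.seed, index])
    rng_eff = np.random.default_rng([cfg.seed, class_idx, index, 1])

    # --- base randomness, drawn in a fixed order ---------------------------
    retina_r = 0.45 * min(h, w) * (1.0 + 0.04 * rng_base.standard_normal())
    tint = rng_base.uniform(-12, 12, size=3)
    disc_cy = h / 2 + rng_base.uniform(-0.08, 0.08) * h
    disc_cx = w / 2 + rng_base.uniform(0.10, 0.22) * w * rng_base.choice([-1, 1])
    disc_r = 0.16 * retina_r * (1.0 + 0.1 * rng_base.standard_normal())
    n_vessels = int(rng_base.integers(2, 5))
    vessel_params = [
        (rng_base.uniform(0, 2 * np.pi), rng_base.uniform(-0.15, 0.15, size=24))
        for _ in range(n_vessels)
    ]
    noise = rng_base.standard_normal((h, w, 1)) * cfg.noise_sigma

    # --- compose the base image -------------------------------------------
    img = np.full((h, w, 3), 8.0)
    retina = _disc_mask(h, w, h / 2, w / 2, retina_r)
    base_colour = np.array([178.0, 92.0, 38.0]) + tint
    img[retina] = base_colour

    # vessels: dark random-walk polylines from the disc centre
    for theta0, jitter in vessel_params:
        y, x, theta = disc_cy, disc_cx, theta0
        for step in range(24):
            theta += jitter[step]
            y += 1.4 * np.sin(theta)
            x += 1.4 * np.cos(theta)
            iy, ix = int(round(y)), int(round(x))
            if 0 <= iy < h and 0 <= ix < w and retina[iy, ix]:
                img[max(0, iy - 1) : iy + 1, max(0, ix - 1) : ix + 1] = [70.0, 26.0, 22.0]

    # optic disc; glaucoma pulls the disc towards the retina centre (a cue
    # the translation-invariant handcrafted descriptors barely see) and
    # modestly enlarges it
    r_eff = disc_r
    cy_eff, cx_eff = disc_cy, disc_cx
    if label == "glaucoma" and cfg.cup_to_disc > 0:
        shift = min(1.0, cfg.cup_to_disc)
        r_eff = disc_r * (1.0 + 0.5 * cfg.cup_to_disc)
        cy_eff = disc_cy + shift * (h / 2 - disc_cy)
        cx_eff = disc_cx + shift * (w / 2 - disc_cx)
    disc = _soft_blob(h, w, cy_eff, cx_eff, r_eff)
    img += disc[..., None] * (np.array([215.0, 188.0, 115.0]) - img) * retina[..., None]

    # --- class effects (separate random stream) ---------------------------
    if label == "diabetic_retinopathy" and cfg.lesion_count > 0 and cfg.lesion_intensity > 0:
        # correlated speckle: zero-mean grain with ~1-px correlation length,
        # strong for local texture descriptors (and coarse enough to survive
        # the enhancement smoothing), invisible to patch-average pooling
        grain = ndimage.gaussian_filter(rng_eff.standard_normal((h, w)), 1.2)
        grain *= 6.0 * cfg.lesion_intensity / grain.std()
        img += (grain * retina)[..., None]
        lo = min(5, cfg.lesion_count)
        n_lesions = int(rng_eff.integers(lo, cfg.lesion_count + 1))
        for k in range(n_lesions):
            ang = rng_eff.uniform(0, 2 * np.pi)
            rad = rng_eff.uniform(0.15, 0.85) * retina_r
            ly = h / 2 + rad * np.sin(ang)
            lx = w / 2 + rad * np.cos(ang)
            lr = rng_eff.uniform(0.7, 1.5)
            colour = (
                np.array([245.0, 232.0, 140.0]) if k % 2 == 0 else np.array([128.0, 12.0, 14.0])
            )
            blob = _soft_blob(h, w, ly, lx, lr) * 0.45 * cfg.lesion_intensity
            img += blob[..., None] * (colour - img) * retina[..., None]

    if label == "cataract" and cfg.haze_strength > 0:
        s = cfg.haze_strength
        for c in range(3):
            img[..., c] = ndimage.gaussian_filter(img[..., c], sigma=2.0 * s)
        img[retina] += s * np.array([85.0, 85.0, 80.0])

    img = img + noise
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def generate_synthetic_dataset(cfg: SyntheticConfig) -> LabeledImageSet:
    """Seeded class-conditioned synthetic fundus dataset.

    Each image holds a circular retina field, an optic disc and a few dark
    vessel curves; class identity only modulates effect sizes (haze for
    cataract, bright/red blobs for diabetic retinopathy, disc enlargement
    for glaucoma).  Identical config -> bit-identical dataset.
    """
    items = []
    for label in CLASSES:
        for i in range(cfg.n_per_class):
            items.append((_synth_image(cfg, label, i), label))
    return LabeledImageSet(items=items)


# ---------------------------------------------------------------------------
# folder I/O
# ---------------------------------------------------------------------------

_IMAGE_SUFFIXES = {".png", ".jpg", ".jpeg"}


def load_image_folder(root) -> LabeledImageSet:
    """Read a class-per-subdirectory image tree into a LabeledImageSet."""
    root = Path(root)
    if not root.is_dir():
        raise InvalidArgumentError(f"not a directory: {root}")
    items = []
    labels_found = []
    for sub in sorted(p for p in root.iterdir() if p.is_dir()):
        labels_found.append(sub.name)
        for f in sorted(sub.iterdir()):
            if f.suffix.lower() in _IMAGE_SUFFIXES:
                items.append((f, sub.name))
    if not items:
        raise InvalidArgumentError(f"no images found under {root}")
    classes = tuple(lab for lab in labels_found if any(l == lab for _, l in items))
    return LabeledImageSet(items=items, classes=classes)


def save_image_set(image_set: LabeledImageSet, root) -> None:
    """Write images as PNG into class-per-subdirectory folders."""
    root = Path(root)
    counters: dict = {}
    for i in range(len(image_set)):
        _, label = image_set.items[i]
        k = counters.get(label, 0)
        counters[label] = k + 1
        out_dir = root / label
        out_dir.mkdir(parents=True, exist_ok=True)
        PILImage.fromarray(image_set.image(i)).save(out_dir / f"{label}_{k:05d}.png")
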