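"""Classical descriptor blocks: GLCM texture statistics, a fuzzy colour
histogram, a 24-neighbour local binary pattern histogram and one-level
wavelet sub-band statistics.

The four blocks concatenate into a fixed 255-dimensional vector per image:
24 (GLCM) + 16 (FCH) + 203 (LBP) + 12 (DWT).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.color import rgb2hsv

from .enhancement import to_luminance
from .errors import InvalidArgumentError

__all__ = [
    "GLCMConfig",
    "LBPConfig",
    "HandcraftedVector",
    "BLOCK_MAP",
    "glcm_features",
    "fch_features",
    "lbp_features",
    "dwt_features",
    "handcrafted_vector",
    "quantise",
]

#: Column-block layout of the concatenated handcrafted vector, in order.
BLOCK_MAP = {"glcm": 24, "fch": 16, "lbp": 203, "dwt": 12}

#: Row/column offsets of the four co-occurrence directions (0, 45, 90, 135 deg)
#: for unit distance; scaled by ``d`` at build time.
_ANGLE_OFFSETS = ((0, 1), (-1, 1), (-1, 0), (-1, -1))

_GLCM_STATS = ("contrast", "correlation", "energy", "homogeneity", "entropy", "dissimilarity")


@dataclass(frozen=True)
class GLCMConfig:
    levels: int = 8
    distance: int = 1
    angles_deg: tuple = (0, 45, 90, 135)
    stats: tuple = _GLCM_STATS

    def __post_init__(self):
        if self.levels < 2 or self.distance < 1:
            raise InvalidArgumentError("levels must be >= 2 and distance >= 1")
        if len(self.angles_deg) * len(self.stats) != 24:
            raise InvalidArgumentError("angles x stats must produce 24 features")


@dataclass(frozen=True)
class LBPConfig:
    neighbours: int = 24
    radius: int = 2
    bins: int = 203

    def __post_init__(self):
        if self.neighbours != (2 * self.radius + 1) ** 2 - 1:
            raise InvalidArgumentError("neighbour count must fill the (2R+1)^2 block minus centre")
        if self.bins < 1:
            raise InvalidArgumentError("bins must be positive")


@dataclass(frozen=True)
class HandcraftedVector:
    values: np.ndarray
    block_map: dict = field(default_factory=lambda: dict(BLOCK_MAP))

    def __len__(self) -> int:
        return len(self.values)

    def block(self, name: str) -> np.ndarray:
        """Slice out one extractor's columns by block name."""
        start = 0
        for key, width in self.block_map.items():
            if key == name:
                return self.values[start : start + width]
            start += width
        raise KeyError(name)


def quantise(img: np.ndarray, levels: int) -> np.ndarray:
    """Quantise an 8-bit grey image into ``levels`` equal-width grey bins."""
    grey = np.clip(np.asarray(img, dtype=float), 0, 255)
    return np.minimum((grey * levels / 256.0).astype(np.int64), levels - 1)


def _cooccurrence(q: np.ndarray, offset: tuple, levels: int) -> np.ndarray:
    """Symmetric normalised co-occurrence matrix for one directional offset."""
    dr, dc = offset
    h, w = q.shape
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    if r0 >= r1 or c0 >= c1:
        raise InvalidArgumentError("image too small for co-occurrence offset")
    a = q[r0:r1, c0:c1].ravel()
    b = q[r0 + dr : r1 + dr, c0 + dc : c1 + dc].ravel()
    mat = np.zeros((levels, levels), dtype=float)
    np.add.at(mat, (a, b), 1.0)
    mat += mat.T  # symmetric: count each pair in both directions
    total = mat.sum()
    return mat / total


def _glcm_stats(p: np.ndarray) -> list:
    levels = p.shape[0]
    i = np.arange(levels)[:, None]
    j = np.arange(levels)[None, :]
    diff = i - j
    contrast = float(np.sum(p * diff**2))
    dissimilarity = float(np.sum(p * np.abs(diff)))
    energy = float(np.sum(p**2))
    homogeneity = float(np.sum(p / (1.0 + diff**2)))
    nz = p[p > 0]
    entropy = float(-np.sum(nz * np.log2(nz)))
    mu_i = float(np.sum(i * p))
    mu_j = float(np.sum(j * p))
    var_i = float(np.sum((i - mu_i) ** 2 * p))
    var_j = float(np.sum((j - mu_j) ** 2 * p))
    if var_i <= 0 or var_j <= 0:
        correlation = 1.0  # zero-variance convention: a single grey level co-occurs with itself
    else:
        correlation = float(np.sum((i - mu_i) * (j - mu_j) * p) / np.sqrt(var_i * var_j))
    return dict(
        contrast=contrast,
        correlation=correlation,
        energy=energy,
        homogeneity=homogeneity,
        entropy=entropy,
        dissimilarity=dissimilarity,
    )


def glcm_features(img: np.ndarray, cfg: GLCMConfig | None = None) -> np.ndarray:
    """24 co-occurrence statistics: 6 per direction over 4 directions.

    The image is quantised to ``cfg.levels`` grey levels; for every
    direction a symmetric normalised co-occurrence matrix at distance
    ``cfg.distance`` is built, and contrast, correlation, energy,
    homogeneity, entropy and dissimilarity are computed in that fixed
    order.  Features are concatenated direction-major.
    """
    cfg = cfg or GLCMConfig()
    img = np.asarray(img)
    if img.ndim != 2:
        raise InvalidArgumentError("glcm_features expects a grey image")
    if min(img.shape) <= cfg.distance:
        raise InvalidArgumentError("image smaller than co-occurrence distance")
    q = quantise(img, cfg.levels)
    out = []
    for angle, (dr, dc) in zip(cfg.angles_deg, _ANGLE_OFFSETS):
        p = _cooccurrence(q, (dr * cfg.distance, dc * cfg.distance), cfg.levels)
        stats = _glcm_stats(p)
        out.extend(stats[name] for name in cfg.stats)
    return np.asarray(out, dtype=float)


def fch_features(img: np.ndarray, bins: int = 16) -> np.ndarray:
    """Fuzzy colour histogram over hue with triangular memberships.

    ``bins`` triangular membership functions are centred evenly on the hue
    circle with full overlap between adjacent bins; every pixel spreads its
    unit mass over the (at most two) bins whose triangles cover its hue.
    The returned histogram sums to 1.
    """
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] < 3:
        raise InvalidArgumentError("fch_features expects an RGB image")
    if bins < 2:
        raise InvalidArgumentError("bins must be >= 2")
    hue = rgb2hsv(np.clip(img[..., :3], 0, 255).astype(np.uint8))[..., 0].ravel()

    width = 1.0 / bins
    centres = np.arange(bins) * width
    # circular distance from each pixel hue to each bin centre
    d = np.abs(hue[:, None] - centres[None, :])
    d = np.minimum(d, 1.0 - d)
    membership = np.clip(1.0 - d / width, 0.0, None)
    hist = membership.sum(axis=0)
    return hist / hist.sum()


def lbp_features(img: np.ndarray, cfg: LBPConfig | None = None) -> np.ndarray:
    """Histogram of 24-bit local binary codes from 5x5 neighbourhoods.

    For every interior pixel the 24 neighbours of its 5x5 block are
    compared to the centre in fixed raster order; neighbour ``p``
    contributes ``2**p`` when it is >= the centre.  Codes are histogrammed
    into ``cfg.bins`` equal-width bins spanning the full code range and
    normalised to sum 1.
    """
    cfg = cfg or LBPConfig()
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise InvalidArgumentError("lbp_features expects a grey image")
    r = cfg.radius
    if img.shape[0] < 2 * r + 1 or img.shape[1] < 2 * r + 1:
        raise InvalidArgumentError("image too small for the neighbourhood block")

    centre = img[r:-r, r:-r]
    codes = np.zeros(centre.shape, dtype=np.int64)
    h, w = img.shape
    p = 0
    for dr in range(-r, r + 1):
        for dc in range(-r, r + 1):
            if dr == 0 and dc == 0:
                continue
            neigh = img[r + dr : h - r + dr, r + dc : w - r + dc]
            codes += (neigh >= centre).astype(np.int64) << p
            p += 1

    max_code = (1 << cfg.neighbours) - 1
    hist, _ = np.histogram(codes.ravel(), bins=cfg.bins, range=(0, max_code))
    return hist / hist.sum()


def _haar_subbands(img: np.ndarray) -> tuple:
    """One-level orthonormal Haar decomposition into (LL, LH, HL, HH).

    Odd dimensions are edge-padded to even before the 2x2 block transform.
    """
    x = np.asarray(img, dtype=float)
    if x.ndim != 2:
        raise InvalidArgumentError("dwt expects a grey image")
    if x.shape[0] < 2 or x.shape[1] < 2:
        raise InvalidArgumentError("image must be at least 2x2")
    pad_r = x.shape[0] % 2
    pad_c = x.shape[1] % 2
    if pad_r or pad_c:
        x = np.pad(x, ((0, pad_r), (0, pad_c)), mode="edge")
    a = x[0::2, 0::2]
    b = x[0::2, 1::2]
    c = x[1::2, 0::2]
    d = x[1::2, 1::2]
    ll = (a + b + c + d) / 2.0
    lh = (a - b + c - d) / 2.0  # horizontal high-pass: vertical-edge detail
    hl = (a + b - c - d) / 2.0  # vertical high-pass: horizontal-edge detail
    hh = (a - b - c + d) / 2.0
    return ll, lh, hl, hh


def dwt_features(img: np.ndarray, wavelet: str = "haar") -> np.ndarray:
    """Mean, standard deviation and variance of each of LL, LH, HL, HH."""
    if wavelet != "haar":
        raise InvalidArgumentError(f"unsupported wavelet {wavelet!r}; only 'haar' is built in")
    out = []
    for band in _haar_subbands(img):
        out.extend([float(band.mean()), float(band.std()), float(band.var())])
    return np.asarray(out, dtype=float)


def handcrafted_vector(img: np.ndarray) -> HandcraftedVector:
    """Concatenate GLCM || FCH || LBP || DWT into the 255-dim descriptor."""
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] < 3:
        raise InvalidArgumentError("handcrafted_vector expects an RGB image")
    grey = np.clip(np.rint(to_luminance(img)), 0, 255)
    values = np.concatenate(
        [
            glcm_features(grey),
            fch_features(img),
            lbp_features(grey),
            dwt_features(grey),
        ]
    )
    return HandcraftedVector(values=values)
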