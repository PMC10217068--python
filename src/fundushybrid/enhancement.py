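"""Image enhancement: neighbourhood averaging, Laplacian sharpening and
filter-quality metrics.

The enhancement pipeline smooths each image with a centre-excluded mean
filter and then sharpens the smoothed image by subtracting its Laplacian
response.  Quality of any filtering step can be quantified with
:func:`filter_quality` (MSE, edge-preservation index, structural content).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import InvalidArgumentError

__all__ = [
    "mean_filter",
    "laplacian",
    "enhance",
    "filter_quality",
    "FilterQualityReport",
    "to_luminance",
]

#: 4-neighbour discrete Laplacian kernel.
LAPLACIAN_KERNEL = np.array([[0, 1, 0], [1, -4, 1], [0, 1, 0]], dtype=float)

#: Rec. 601 luma weights used whenever an RGB image must be collapsed to grey.
LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class FilterQualityReport:
    """Numeric comparison of an original image against a filtered version."""

    mse: float
    epi: float
    sc: float


def _check_image(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.size == 0:
        raise InvalidArgumentError("empty image")
    if img.ndim not in (2, 3):
        raise InvalidArgumentError(f"expected 2-D or 3-D image, got ndim={img.ndim}")
    if img.ndim == 3 and img.shape[2] not in (3, 4):
        raise InvalidArgumentError(f"expected RGB(A) channels last, got shape {img.shape}")
    return img


def to_luminance(img: np.ndarray) -> np.ndarray:
    """Collapse an RGB image to a grey (luminance) array; grey passes through."""
    img = _check_image(img)
    if img.ndim == 2:
        return img.astype(float)
    return img[..., :3].astype(float) @ LUMA_WEIGHTS


def mean_filter(img: np.ndarray, window: int = 5) -> np.ndarray:
    """Replace every pixel by the mean of its ``window**2 - 1`` neighbours.

    The centre pixel is excluded from its own average.  Borders are handled
    by edge replication.  Output is rounded to the nearest integer and
    clipped to [0, 255]; shape is preserved.
    """
    img = _check_image(img)
    if window < 3 or window % 2 == 0:
        raise InvalidArgumentError(f"window must be an odd integer >= 3, got {window}")

    # integer accumulation keeps the .5 rounding boundary exact for
    # integer-valued inputs regardless of summation order
    kernel = np.ones((window, window), dtype=np.int64)
    kernel[window // 2, window // 2] = 0

    integral = np.all(np.mod(img, 1) == 0)
    work = img.astype(np.int64) if integral else np.asarray(img, dtype=float)
    n = window * window - 1

    def _one(channel):
        total = ndimage.correlate(channel, kernel.astype(channel.dtype), mode="nearest")
        return total / n

    if img.ndim == 2:
        out = _one(work)
    else:
        out = np.stack([_one(work[..., c]) for c in range(img.shape[2])], axis=-1)
    return np.clip(np.rint(out), 0, 255).astype(img.dtype if img.dtype.kind == "u" else np.int64)


def laplacian(img: np.ndarray) -> np.ndarray:
    """Signed 4-neighbour Laplacian response with replicated borders.

    RGB input is converted to luminance first; the result is a signed float
    array of the same height and width.
    """
    grey = to_luminance(img)
    return ndimage.correlate(grey, LAPLACIAN_KERNEL, mode="nearest")


def _laplacian_channel(channel: np.ndarray) -> np.ndarray:
    return ndimage.correlate(channel.astype(float), LAPLACIAN_KERNEL, mode="nearest")


def enhance(img: np.ndarray, window: int = 5) -> np.ndarray:
    """Sharpen the smoothed image: ``smoothed - laplacian(smoothed)``.

    Applied per channel for RGB input.  Output values are rounded and
    clipped to [0, 255]; shape and dtype family are preserved.
    """
    img = _check_image(img)
    smoothed = mean_filter(img, window=window)
    if img.ndim == 2:
        out = smoothed.astype(float) - _laplacian_channel(smoothed)
    else:
        out = np.empty(smoothed.shape, dtype=float)
        for c in range(smoothed.shape[2]):
            ch = smoothed[..., c].astype(float)
            out[..., c] = ch - _laplacian_channel(ch)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def filter_quality(original: np.ndarray, filtered: np.ndarray) -> FilterQualityReport:
    """MSE, edge-preservation index and structural content of a filter output.

    * ``mse``: mean squared pixel difference (0 iff identical).
    * ``epi``: Pearson correlation between the Laplacian edge maps of the two
      images (1 for identical edge maps).  If both edge maps are constant the
      index is 1 when they are equal and 0 otherwise.
    * ``sc``: structural content, ``sum(original**2) / sum(filtered**2)``.
    """
    original = _check_image(original)
    filtered = _check_image(filtered)
    if original.shape != filtered.shape:
        raise InvalidArgumentError(
            f"shape mismatch: {original.shape} vs {filtered.shape}"
        )

    a = original.astype(float)
    b = filtered.astype(float)
    mse = float(np.mean((a - b) ** 2))

    ea = laplacian(original).ravel()
    eb = laplacian(filtered).ravel()
    if ea.std() == 0.0 or eb.std() == 0.0:
        epi = 1.0 if np.array_equal(ea, eb) else 0.0
    else:
        epi = float(np.corrcoef(ea, eb)[0, 1])

    denom = float(np.sum(b**2))
    if denom == 0.0:
        raise InvalidArgumentError("filtered image is all zero; SC undefined")
    sc = float(np.sum(a**2)) / denom
    return FilterQualityReport(mse=mse, epi=epi, sc=sc)
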