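"""Deep feature extraction through a pluggable backbone, plus PCA reduction.

Two backends exist:

* ``toy`` — a deterministic, dependency-free stand-in: images are resized,
  pooled over a patch grid (mean/std/max per channel per patch) and pushed
  through a fixed-seed random projection with a tanh squashing.  The
  projection seed derives from the backbone name, so differently named toy
  specs behave like distinct feature extractors.
* ``pretrained`` — reserved for torchvision-style backbones; unavailable in
  this environment and raises :class:`BackboneUnavailableError` naming the
  spec so callers fail loudly rather than silently degrading.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from .errors import BackboneUnavailableError, InvalidArgumentError

__all__ = [
    "BackboneSpec",
    "PCAModel",
    "extract_deep_features",
    "fit_pca",
    "apply_pca",
    "effective_components",
]

_PATCH_GRID = 6  # pooling grid per side for the toy backbone


@dataclass(frozen=True)
class BackboneSpec:
    """Identifies a feature extractor and its fixed output geometry."""

    name: str = "toy"
    output_dim: int = 2048
    input_size: tuple = (224, 224)
    backend: str = "toy"

    def __post_init__(self):
        if self.output_dim < 1:
            raise InvalidArgumentError("output_dim must be positive")
        if self.backend not in ("toy", "pretrained"):
            raise InvalidArgumentError(f"unknown backend {self.backend!r}")


def _toy_projection(spec: BackboneSpec, in_dim: int) -> np.ndarray:
    """Fixed Gaussian projection matrix derived from the spec name."""
    digest = hashlib.sha256(f"{spec.name}:{spec.output_dim}".encode()).digest()
    seed = int.from_bytes(digest[:8], "little")
    rng = np.random.default_rng(seed)
    return rng.standard_normal((spec.output_dim, in_dim)) / np.sqrt(in_dim)


def _pool_patches(img: np.ndarray, input_size: tuple) -> np.ndarray:
    """Resize to the backbone input size and average-pool a patch grid.

    Emits the per-channel mean of every cell of a
    ``_PATCH_GRID x _PATCH_GRID`` grid as a flat descriptor — a crude
    stand-in for a convolutional feature map after global average pooling:
    sensitive to layout, colour and brightness, largely blind to zero-mean
    fine texture.
    """
    arr = np.asarray(img, dtype=float)
    if arr.ndim == 2:
        arr = arr[..., None]
    arr = arr[..., :3] / 255.0
    arr = resize(arr, (*input_size, arr.shape[2]), anti_aliasing=True, preserve_range=True)
    h, w, c = arr.shape
    rows = np.linspace(0, h, _PATCH_GRID + 1).astype(int)
    cols = np.linspace(0, w, _PATCH_GRID + 1).astype(int)
    desc = []
    for i in range(_PATCH_GRID):
        for j in range(_PATCH_GRID):
            patch = arr[rows[i] : rows[i + 1], cols[j] : cols[j + 1]]
            desc.append(patch.reshape(-1, c).mean(axis=0))
    return np.concatenate(desc)


def extract_deep_features(images, spec: BackboneSpec | None = None) -> np.ndarray:
    """N x output_dim feature matrix; deterministic for a fixed spec."""
    spec = spec or BackboneSpec()
    if spec.backend == "pretrained":
        raise BackboneUnavailableError(
            f"pretrained backbone {spec.name!r} requires torchvision weights, "
            "which are not available in this environment; use a toy spec"
        )
    images = list(images)
    if not images:
        raise InvalidArgumentError("no images given")
    descs = np.stack([_pool_patches(im, spec.input_size) for im in images])
    proj = _toy_projection(spec, descs.shape[1])
    return np.tanh(descs @ proj.T)


@dataclass(frozen=True)
class PCAModel:
    n_components: int
    components: np.ndarray  # (n_components, D)
    mean: np.ndarray  # (D,)
    explained_variance_ratio: np.ndarray


def effective_components(requested: int, n_samples: int, n_features: int) -> int:
    """Cap a requested component count at min(N-1, D); never silent at call sites."""
    return min(requested, n_samples - 1, n_features)


def fit_pca(X: np.ndarray, n_components: int) -> PCAModel:
    """Centred PCA with a deterministic sign convention.

    Each component is flipped so that its largest-magnitude loading is
    positive, making transformed scores reproducible across runs.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise InvalidArgumentError("X must be a 2-D matrix")
    if not np.all(np.isfinite(X)):
        raise InvalidArgumentError("X must be finite")
    n, d = X.shape
    if n_components < 1 or n_components > min(n - 1, d):
        raise InvalidArgumentError(
            f"n_components={n_components} out of range for shape {X.shape} "
            f"(max {min(n - 1, d)})"
        )

    if np.all(X.var(axis=0) == 0):
        from .errors import DegenerateInputError

        raise DegenerateInputError("input matrix has zero variance; PCA is degenerate")

    from sklearn.decomposition import PCA

    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(X)
    comps = pca.components_.copy()
    for k in range(comps.shape[0]):
        pivot = np.argmax(np.abs(comps[k]))
        if comps[k, pivot] < 0:
            comps[k] = -comps[k]
    return PCAModel(
        n_components=n_components,
        components=comps,
        mean=pca.mean_.copy(),
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
    )


def apply_pca(model: PCAModel, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.mean.shape[0]:
        raise InvalidArgumentError(
            f"feature width {X.shape} does not match PCA model ({model.mean.shape[0]})"
        )
    return (X - model.mean) @ model.components.T
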