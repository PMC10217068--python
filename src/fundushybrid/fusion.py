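"""Feature-level fusion with exact dimensional contracts.

Reference widths per fusion mode (for the full-size dataset):

========================  =====
mode                      width
========================  =====
single_pca                  450
fuse_before_pca             710
fuse_after_pca              900
cnn_plus_handcrafted        705
========================  =====

On toy-sized inputs where ``N - 1`` is smaller than a requested PCA width
the component count is capped at ``N - 1``; the cap is reported through the
logger, never applied silently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .deep_features import apply_pca, effective_components, fit_pca
from .errors import InvalidArgumentError

__all__ = [
    "FusionPlan",
    "REFERENCE_DIMS",
    "fuse_before_pca",
    "fuse_after_pca",
    "fuse_cnn_handcrafted",
]

logger = logging.getLogger(__name__)

REFERENCE_DIMS = {
    "single_pca": 450,
    "fuse_before_pca": 710,
    "fuse_after_pca": 900,
    "cnn_plus_handcrafted": 705,
}


@dataclass(frozen=True)
class FusionPlan:
    mode: str

    def __post_init__(self):
        if self.mode not in REFERENCE_DIMS:
            raise InvalidArgumentError(f"unknown fusion mode {self.mode!r}")

    @property
    def expected_width(self) -> int:
        return REFERENCE_DIMS[self.mode]


def _as_matrix(X, name: str) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise InvalidArgumentError(f"{name} must be a 2-D matrix")
    return X


def fuse_before_pca(A: np.ndarray, B: np.ndarray, pca_dim: int = 710):
    """Concatenate two backbone blocks then reduce the joint matrix.

    Returns ``(fused, pca_model)`` where ``fused`` has ``pca_dim`` columns
    (capped at N-1 with a logged warning on toy-sized inputs).
    """
    A = _as_matrix(A, "A")
    B = _as_matrix(B, "B")
    if A.shape[0] != B.shape[0]:
        raise InvalidArgumentError(f"row mismatch: {A.shape[0]} vs {B.shape[0]}")
    joint = np.hstack([A, B])
    eff = effective_components(pca_dim, joint.shape[0], joint.shape[1])
    if eff < pca_dim:
        logger.warning(
            "fuse_before_pca: requested %d components capped at %d (N=%d)",
            pca_dim,
            eff,
            joint.shape[0],
        )
    model = fit_pca(joint, eff)
    return apply_pca(model, joint), model


def fuse_after_pca(A_red: np.ndarray, B_red: np.ndarray, per_model_dim: int = 450) -> np.ndarray:
    """Concatenate two already-reduced blocks, A first then B."""
    A_red = _as_matrix(A_red, "A_red")
    B_red = _as_matrix(B_red, "B_red")
    if A_red.shape[0] != B_red.shape[0]:
        raise InvalidArgumentError(f"row mismatch: {A_red.shape[0]} vs {B_red.shape[0]}")
    for name, block in (("A_red", A_red), ("B_red", B_red)):
        if block.shape[1] != per_model_dim:
            raise InvalidArgumentError(
                f"{name} width {block.shape[1]} != expected per-model width {per_model_dim}"
            )
    return np.hstack([A_red, B_red])


def fuse_cnn_handcrafted(
    C_red: np.ndarray,
    H: np.ndarray,
    cnn_dim: int = 450,
    hand_dim: int = 255,
) -> np.ndarray:
    """Concatenate a reduced CNN block (first) with the handcrafted block."""
    C_red = _as_matrix(C_red, "C_red")
    H = _as_matrix(H, "H")
    if C_red.shape[0] != H.shape[0]:
        raise InvalidArgumentError(f"row mismatch: {C_red.shape[0]} vs {H.shape[0]}")
    if C_red.shape[1] != cnn_dim:
        raise InvalidArgumentError(f"CNN block width {C_red.shape[1]} != expected {cnn_dim}")
    if H.shape[1] != hand_dim:
        raise InvalidArgumentError(f"handcrafted width {H.shape[1]} != expected {hand_dim}")
    return np.hstack([C_red, H])
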