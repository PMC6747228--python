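"""RBF Gram matrices per feature view and their weighted combination.

Each feature view is turned into a Gaussian kernel
``K_ij = exp(-gamma * ||x_i - x_j||^2)``; a convex combination of the
per-view kernels (weights from the MKL step, or uniform for the mean-weight
baseline) is the kernel the classifier consumes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .exceptions import ValidationError
from .features import FeatureMatrix


@dataclass
class KernelMatrix:
    """An M×N Gram matrix tagged with its source view and bandwidth.

    Square matrices with ``row_ids == col_ids`` are train-train kernels and
    are kept exactly symmetric; rectangular ones are test-train kernels.
    """

    values: np.ndarray
    view: str
    row_ids: tuple[str, ...]
    col_ids: tuple[str, ...]
    gamma: Optional[float] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.row_ids = tuple(self.row_ids)
        self.col_ids = tuple(self.col_ids)
        if self.values.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValidationError(
                f"kernel {self.view!r}: shape {self.values.shape} does not "
                f"match ids ({len(self.row_ids)}×{len(self.col_ids)})"
            )

    @property
    def is_square(self) -> bool:
        return self.row_ids == self.col_ids

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def rbf_kernel(
    X: FeatureMatrix,
    Y: Optional[FeatureMatrix] = None,
    *,
    gamma: float,
) -> KernelMatrix:
    """Gaussian kernel between the rows of X and Y (Y defaults to X).

    The squared Euclidean distances are computed exactly (``cdist``), so the
    X-vs-X kernel has an exact unit diagonal and exact symmetry.
    """
    if gamma <= 0:
        raise ValidationError(f"gamma must be positive, got {gamma}")
    if Y is None:
        Y = X
    if X.view != Y.view:
        raise ValidationError(f"view mismatch: {X.view!r} vs {Y.view!r}")
    if X.dim != Y.dim:
        raise ValidationError(
            f"dimension mismatch for view {X.view!r}: {X.dim} vs {Y.dim}"
        )
    sq = cdist(X.values, Y.values, metric="sqeuclidean")
    K = np.exp(-gamma * sq)
    if X.ids == Y.ids:
        K = 0.5 * (K + K.T)
        np.fill_diagonal(K, 1.0)
    return KernelMatrix(values=K, view=X.view, row_ids=X.ids, col_ids=Y.ids,
                        gamma=gamma)


def default_gamma(
    X: FeatureMatrix,
    *,
    max_rows: int = 500,
    seed: int = 0,
) -> float:
    """Median heuristic for the kernel bandwidth: 1 / median of pairwise
    squared distances.  Above ``max_rows`` rows a seeded subsample keeps the
    cost quadratic in ``max_rows`` only."""
    values = X.values
    if values.shape[0] > max_rows:
        rng = np.random.default_rng(seed)
        idx = rng.choice(values.shape[0], size=max_rows, replace=False)
        values = values[np.sort(idx)]
    if values.shape[0] < 2:
        raise ValidationError("need at least 2 rows to pick a bandwidth")
    sq = cdist(values, values, metric="sqeuclidean")
    med = float(np.median(sq[np.triu_indices_from(sq, k=1)]))
    if med == 0.0:
        raise ValidationError(
            f"view {X.view!r}: all rows identical — pass an explicit gamma"
        )
    return 1.0 / med


def combine_kernels(
    kernels: Sequence[KernelMatrix],
    weights: Sequence[float],
) -> KernelMatrix:
    """Entrywise weighted sum of aligned kernels, tagged ``combined``."""
    if not kernels:
        raise ValidationError("no kernels to combine")
    if len(kernels) != len(weights):
        raise ValidationError(
            f"{len(kernels)} kernels but {len(weights)} weights"
        )
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValidationError(f"negative kernel weight in {w}")
    first = kernels[0]
    for k in kernels[1:]:
        if k.shape != first.shape or k.row_ids != first.row_ids \
                or k.col_ids != first.col_ids:
            raise ValidationError(
                f"kernel {k.view!r} is not aligned with {first.view!r}"
            )
    combined = np.zeros(first.shape)
    for wk, k in zip(w, kernels):
        combined += wk * k.values
    return KernelMatrix(values=combined, view="combined",
                        row_ids=first.row_ids, col_ids=first.col_ids)
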