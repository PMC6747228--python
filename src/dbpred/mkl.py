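"""Multiple-kernel learning by ideal-kernel alignment.

Given H train-train kernels K_h and ±1 labels y, find simplex weights ω
minimizing

    || Σ_h ω_h K_h − y yᵀ ||_F²  +  λ ||ω||²
    s.t.  ω_h ≥ 0,  Σ_h ω_h = 1.

Expanding the Frobenius norm reduces this to an H-dimensional quadratic
program with Gram matrix M_hk = ⟨K_h, K_k⟩_F and linear term
b_h = ⟨K_h, yyᵀ⟩_F = yᵀ K_h y.  With H small (four feature views here) the
QP is solved exactly by enumerating the 2^H − 1 possible support patterns,
solving the equality-constrained system on each, and keeping the feasible
minimum — deterministic, no iterative solver to tune.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np

from .exceptions import ValidationError
from .kernels import KernelMatrix

_SYM_TOL = 1e-10


@dataclass
class MKLSolution:
    """Simplex weights with the achieved alignment objective."""

    weights: np.ndarray
    objective: float
    lam: float

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights < -1e-9) or abs(self.weights.sum() - 1) > 1e-9:
            raise ValidationError(
                f"weights {self.weights} violate the simplex constraints"
            )


def _check_inputs(kernels: Sequence[KernelMatrix], y: np.ndarray) -> np.ndarray:
    if not kernels:
        raise ValidationError("need at least one kernel")
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    if not np.all(np.isin(y, (-1.0, 1.0))):
        raise ValidationError("labels must be ±1")
    ids = kernels[0].row_ids
    for k in kernels:
        if k.shape != (n, n):
            raise ValidationError(
                f"kernel {k.view!r} has shape {k.shape}, expected ({n},{n})"
            )
        if k.row_ids != ids or k.col_ids != ids:
            raise ValidationError(f"kernel {k.view!r} ids not aligned")
        if np.max(np.abs(k.values - k.values.T)) > _SYM_TOL:
            raise ValidationError(f"kernel {k.view!r} is not symmetric")
    return y


def _qp_terms(kernels, y):
    """Gram matrix M, linear term b and constant ||yyᵀ||_F² of the QP."""
    H = len(kernels)
    M = np.empty((H, H))
    b = np.empty(H)
    for h, kh in enumerate(kernels):
        b[h] = y @ kh.values @ y
        for k in range(h, H):
            M[h, k] = M[k, h] = float(np.sum(kh.values * kernels[k].values))
    const = float(len(y)) ** 2  # ||yyᵀ||_F² for ±1 labels
    return M, b, const


def mkl_objective(
    kernels: Sequence[KernelMatrix],
    y,
    weights,
    lam: float,
) -> float:
    """Alignment objective ‖Σ ω_h K_h − yyᵀ‖²_F + λ‖ω‖² at given weights."""
    y = _check_inputs(kernels, y)
    w = np.asarray(weights, dtype=float)
    if w.shape != (len(kernels),):
        raise ValidationError(
            f"{len(kernels)} kernels but weights of shape {w.shape}"
        )
    combined = sum(wh * k.values for wh, k in zip(w, kernels))
    resid = combined - np.outer(y, y)
    return float(np.sum(resid * resid) + lam * np.dot(w, w))


def optimize_weights(
    kernels: Sequence[KernelMatrix],
    y,
    lam: float = 1.0,
    *,
    scale_lambda: bool = True,
) -> MKLSolution:
    """Solve the simplex-constrained alignment QP exactly.

    ``lam`` is the ridge strength on the weights.  Because the Frobenius
    inner products ⟨K_h, K_k⟩_F grow like N², ``scale_lambda=True`` (default)
    interprets ``lam`` in those units, multiplying it by the mean of the
    ⟨K_h, K_h⟩_F scales so the same nominal value behaves comparably across
    dataset sizes; pass ``scale_lambda=False`` to use ``lam`` verbatim.

    Returns the weights, the achieved objective (at the effective λ) and the
    effective λ itself.
    """
    y = _check_inputs(kernels, y)
    if lam < 0:
        raise ValidationError(f"lambda must be non-negative, got {lam}")
    H = len(kernels)
    M, b, const = _qp_terms(kernels, y)
    lam_eff = lam * float(np.mean(np.diag(M))) if scale_lambda else lam
    Q = M + lam_eff * np.eye(H)

    best_w = None
    best_obj = np.inf
    for size in range(1, H + 1):
        for support in combinations(range(H), size):
            idx = list(support)
            Qs = Q[np.ix_(idx, idx)]
            bs = b[idx]
            # KKT system of  min ωᵀQω − 2bᵀω  s.t. Σω = 1  on the support
            A = np.zeros((size + 1, size + 1))
            A[:size, :size] = 2.0 * Qs
            A[:size, size] = 1.0
            A[size, :size] = 1.0
            rhs = np.concatenate([2.0 * bs, [1.0]])
            try:
                sol = np.linalg.solve(A, rhs)
            except np.linalg.LinAlgError:
                sol, *_ = np.linalg.lstsq(A, rhs, rcond=None)
            ws = sol[:size]
            if np.any(ws < -1e-12):
                continue
            w = np.zeros(H)
            w[idx] = np.clip(ws, 0.0, None)
            w /= w.sum()
            obj = float(w @ Q @ w - 2.0 * b @ w + const)
            if obj < best_obj - 1e-15:
                best_obj = obj
                best_w = w
    assert best_w is not None  # singletons are always feasible
    return MKLSolution(weights=best_w, objective=best_obj, lam=lam_eff)
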