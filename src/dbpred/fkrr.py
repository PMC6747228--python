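"""Fuzzy kernel ridge regression.

Plain kernel ridge regression (KRR) fits dual coefficients
``α = (K + (1/C) I)^{-1} y``.  The fuzzy variant downweights likely
outliers: each training sample t gets a membership D_tt ∈ (0,1) — a
sigmoid of a class-contrast kernel score — and the ridge is rescaled per
sample,

    α = (K + (1/C) D^{-2})^{-1} y ,

so low-membership samples are regularized harder and pull the decision
boundary less.  With D = I this reduces exactly to KRR.  Linear systems are
solved by symmetric factorization, never by forming an explicit inverse.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import scipy.linalg

from .exceptions import ValidationError
from .features import FeatureMatrix
from .kernels import KernelMatrix, combine_kernels, default_gamma, rbf_kernel
from .mkl import optimize_weights


def _check_square(K: KernelMatrix, y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    if K.shape != (n, n):
        raise ValidationError(
            f"kernel shape {K.shape} does not match {n} labels"
        )
    return y


def membership_scores(K: KernelMatrix, y) -> np.ndarray:
    """Class-contrast score of each training point on a train-train kernel:

        score_t = (1/N²) ( Σ_{y_i = y_t} K[t,i] − Σ_{y_i ≠ y_t} K[t,i] )

    The self-similarity term i = t belongs to the same-class sum.  Points
    that sit close (in kernel space) to their own class and far from the
    other get high scores; likely outliers get low ones.
    """
    y = _check_square(K, y)
    if not np.all(np.isin(y, (-1.0, 1.0))):
        raise ValidationError("labels must be ±1")
    n = y.shape[0]
    same = (y[None, :] == y[:, None])
    signed = np.where(same, K.values, -K.values)
    return signed.sum(axis=1) / (n * n)


def memberships_from_scores(scores, *, standardize: bool = False) -> np.ndarray:
    """Squash scores into fuzzy memberships ``D_tt = 1 / (1 + exp(−score))``.

    Strictly increasing, range (0,1).  Raw class-contrast scores scale like
    O(1/N), so for large N they crowd around 0 and all memberships around
    0.5; ``standardize=True`` z-scores them first, which spreads the
    memberships over (0,1) at any sample size (an opt-in deviation from the
    verbatim formula, documented in the methods note).
    """
    s = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(s)):
        raise ValidationError("non-finite membership score")
    if standardize:
        sd = s.std()
        s = (s - s.mean()) / sd if sd > 0 else np.zeros_like(s)
    return 1.0 / (1.0 + np.exp(-s))


def fit_krr(K: KernelMatrix, y, C: float) -> np.ndarray:
    """Dual coefficients of kernel ridge regression, α = (K + (1/C) I)⁻¹ y."""
    y = _check_square(K, y)
    if C <= 0:
        raise ValidationError(f"C must be positive, got {C}")
    A = K.values + (1.0 / C) * np.eye(len(y))
    return _solve_sym(A, y)


@dataclass
class FKRRModel:
    """A trained fuzzy kernel ridge regression model.

    Carries everything prediction needs: dual coefficients ``alpha``,
    memberships ``D`` (diagonal), the MKL weights ``omega`` and per-view
    bandwidths ``gammas`` used to build the training kernel, and the
    training feature matrices so test-vs-train kernels can be reproduced.
    """

    alpha: np.ndarray
    D: np.ndarray
    C: float
    omega: np.ndarray
    views: tuple[str, ...] = ()
    gammas: dict = field(default_factory=dict)
    train_ids: tuple[str, ...] = ()
    train_features: dict = field(default_factory=dict)
    lam: float = 0.0
    fuzzy: bool = True
    standardize_scores: bool = False

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.D = np.asarray(self.D, dtype=float)
        self.omega = np.asarray(self.omega, dtype=float)

    def test_kernel(self, test_views: Mapping[str, FeatureMatrix]) -> KernelMatrix:
        """Combined M×N kernel between new samples and the training set."""
        kernels = []
        for view in self.views:
            if view not in test_views:
                raise ValidationError(f"missing test features for view {view!r}")
            train_fm = FeatureMatrix(view=view,
                                     values=self.train_features[view],
                                     ids=self.train_ids)
            kernels.append(
                rbf_kernel(test_views[view], train_fm, gamma=self.gammas[view])
            )
        return combine_kernels(kernels, self.omega)

    def predict_views(self, test_views: Mapping[str, FeatureMatrix]):
        return predict(self.test_kernel(test_views), self.alpha)


def fit_fkrr(K: KernelMatrix, y, C: float, D) -> FKRRModel:
    """Closed-form fuzzy KRR fit, α = (K + (1/C) D⁻²)⁻¹ y."""
    y = _check_square(K, y)
    if C <= 0:
        raise ValidationError(f"C must be positive, got {C}")
    D = np.asarray(D, dtype=float)
    if D.ndim != 1 or D.shape != y.shape:
        raise ValidationError("D must be a vector of per-sample memberships")
    if np.any(D <= 0) or np.any(D > 1):
        raise ValidationError("memberships must lie in (0, 1]")
    A = K.values + (1.0 / C) * np.diag(D ** -2)
    alpha = _solve_sym(A, y)
    return FKRRModel(alpha=alpha, D=D, C=C, omega=np.array([1.0]),
                     train_ids=K.row_ids)


def _solve_sym(A: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Symmetric solve with a conditioning diagnostic."""
    try:
        alpha = scipy.linalg.solve(A, y, assume_a="sym")
    except scipy.linalg.LinAlgError as exc:
        raise ValidationError(f"singular ridge system: {exc}") from None
    resid = np.linalg.norm(A @ alpha - y)
    if not np.all(np.isfinite(alpha)) or resid > 1e-6 * max(1.0, np.linalg.norm(y)):
        raise ValidationError(
            f"ridge system is numerically singular (residual {resid:.3e})"
        )
    return alpha


def predict(K_test: KernelMatrix, alpha) -> tuple[np.ndarray, np.ndarray]:
    """Decision values ``K_test @ α`` and hard ±1 labels (sign, ties → +1)."""
    alpha = np.asarray(alpha, dtype=float)
    if K_test.shape[1] != alpha.shape[0]:
        raise ValidationError(
            f"kernel has {K_test.shape[1]} columns but alpha has "
            f"{alpha.shape[0]} entries"
        )
    decisions = K_test.values @ alpha
    labels = np.where(decisions >= 0, 1, -1)
    return labels, decisions


@dataclass
class PipelineParams:
    """Hyperparameters of the full training pipeline (all optional).

    ``gammas`` maps view name → RBF bandwidth; views left unset use the
    median heuristic.  ``C`` is the ridge constant, ``lam`` the MKL weight
    ridge.  ``fuzzy=False`` forces D = I (plain KRR on the combined kernel);
    ``mean_weights=True`` skips MKL and uses uniform kernel weights.
    """

    C: float = 1.0
    lam: float = 1.0
    gammas: dict = field(default_factory=dict)
    lg: int = 10
    lag_max: int = 15
    fuzzy: bool = True
    standardize_scores: bool = False
    mean_weights: bool = False
    gamma_seed: int = 0


def train_full_pipeline(
    views: Mapping[str, FeatureMatrix],
    y,
    params: Optional[PipelineParams] = None,
) -> FKRRModel:
    """Train end to end from feature views:

    per-view RBF kernels → MKL weights → combined kernel → fuzzy
    memberships on the combined kernel → closed-form FKRR fit.
    """
    params = params or PipelineParams()
    if not views:
        raise ValidationError("no feature views supplied")
    view_names = tuple(views)
    y = np.asarray(y, dtype=float)

    first = views[view_names[0]]
    ids = first.ids
    for fm in views.values():
        if fm.ids != ids:
            raise ValidationError(f"view {fm.view!r} rows not aligned")
    if y.shape[0] != first.n:
        raise ValidationError("label count does not match feature rows")

    gammas = {}
    kernels = []
    for name in view_names:
        g = params.gammas.get(name)
        if g is None:
            g = default_gamma(views[name], seed=params.gamma_seed)
        gammas[name] = g
        kernels.append(rbf_kernel(views[name], gamma=g))

    if params.mean_weights or len(kernels) == 1:
        omega = np.full(len(kernels), 1.0 / len(kernels))
        lam_eff = params.lam
    else:
        sol = optimize_weights(kernels, y, lam=params.lam)
        omega, lam_eff = sol.weights, sol.lam

    K_comb = combine_kernels(kernels, omega)
    if params.fuzzy:
        scores = membership_scores(K_comb, y)
        D = memberships_from_scores(scores,
                                    standardize=params.standardize_scores)
    else:
        D = np.ones(len(y))

    A = K_comb.values + (1.0 / params.C) * np.diag(D ** -2)
    alpha = _solve_sym(A, y)

    return FKRRModel(
        alpha=alpha,
        D=D,
        C=params.C,
        omega=omega,
        views=view_names,
        gammas=gammas,
        train_ids=ids,
        train_features={name: views[name].values for name in view_names},
        lam=lam_eff,
        fuzzy=params.fuzzy,
        standardize_scores=params.standardize_scores,
    )
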