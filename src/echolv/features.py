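"""Regressor blocks: PCA image scores and the periodic spline time basis.

Each boundary model regresses anchor radii on two blocks: (1) scores of the
short-axis images in a low-dimensional principal-component subspace fitted on
training images only, and (2) a periodic cubic B-spline basis evaluated at
the cardiac-cycle phase, which captures the average anchor trajectory across
the cycle.  The spline basis is an unpenalized expansion (the models are fit
by ordinary least squares); it is periodic because the cardiac cycle is.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.interpolate import BSpline
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)

Scope = Literal["per-slice", "combined"]


class ImagePCA(TransformerMixin, BaseEstimator):
    """Principal-component compression of vectorized images.

    Thin sklearn-style transformer over :class:`sklearn.decomposition.PCA`:
    components are the leading eigenvectors of the training covariance,
    ordered by decreasing explained variance.  ``n_components`` is clipped to
    ``min(n_samples - 1, n_features)`` with a logged warning.

    Attributes (after fit): ``mean_``, ``components_`` (k x p, orthonormal),
    ``explained_variance_``, ``n_components_``.
    """

    def __init__(self, n_components: int = 8, random_state: int = 0):
        self.n_components = n_components
        self.random_state = random_state

    def fit(self, X: np.ndarray, y=None) -> "ImagePCA":
        X = np.asarray(X)
        if X.ndim != 2:
            X = X.reshape(X.shape[0], -1)
        n, p = X.shape
        if n < 2:
            raise ValueError("PCA requires at least 2 training images")
        k = int(self.n_components)
        k_feasible = min(n - 1, p)
        if k > k_feasible:
            logger.warning(
                "n_components=%d exceeds min(n_samples-1, n_features)=%d; clipping",
                k, k_feasible,
            )
            k = k_feasible
        self._pca = PCA(n_components=k, random_state=self.random_state)
        self._pca.fit(X)
        self.mean_ = self._pca.mean_
        self.components_ = self._pca.components_
        self.explained_variance_ = self._pca.explained_variance_
        self.n_components_ = k
        self.n_features_in_ = p
        return self

    def transform(self, X: np.ndarray, k: int | None = None) -> np.ndarray:
        """Scores of ``X`` on the first ``k`` components (default: all fitted)."""
        X = np.asarray(X)
        if X.ndim != 2:
            X = X.reshape(X.shape[0], -1)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"images have {X.shape[1]} pixels; basis was fitted on "
                f"{self.n_features_in_}"
            )
        k = self.n_components_ if k is None else int(k)
        if k > self.n_components_:
            raise ValueError(f"k={k} exceeds the fitted component count {self.n_components_}")
        return (X - self.mean_) @ self.components_[:k].T

    def inverse_transform(self, scores: np.ndarray) -> np.ndarray:
        k = scores.shape[1]
        return scores @ self.components_[:k] + self.mean_


@dataclass
class ImageBasis:
    """Fitted PCA basis for slice-stack images.

    ``scope="per-slice"`` holds one :class:`ImagePCA` per slice level and
    produces scores of shape (n, n_slices, k); ``scope="combined"`` holds a
    single PCA over the concatenated four-slice pixel vector and produces
    scores of shape (n, k).
    """

    scope: Scope
    blocks: list[ImagePCA]
    image_shape: tuple[int, ...]
    n_slices: int

    @property
    def k_max(self) -> int:
        return min(b.n_components_ for b in self.blocks)

    def project(self, images: np.ndarray, k: int | None = None) -> np.ndarray:
        """Project slice-stack images ``(n, n_slices, ny, nx)`` to scores."""
        X = np.asarray(images)
        X = X.reshape(X.shape[0], self.n_slices, -1)
        k = self.k_max if k is None else int(k)
        if self.scope == "combined":
            return self.blocks[0].transform(X.reshape(X.shape[0], -1), k=k)
        return np.stack(
            [self.blocks[s].transform(X[:, s, :], k=k) for s in range(self.n_slices)],
            axis=1,
        )


def fit_image_basis(training_images: np.ndarray, k_max: int,
                    scope: Scope = "per-slice", random_state: int = 0) -> ImageBasis:
    """Fit a PCA basis on training slice stacks ``(n, n_slices, ny, nx)``.

    For ``scope="combined"`` the slices of each frame are concatenated into a
    single pixel vector before the decomposition (one joint subspace); for
    ``scope="per-slice"`` each slice level gets its own subspace.  Validation
    and test images must never enter here.
    """
    X = np.asarray(training_images)
    if X.ndim < 3:
        raise ValueError("expected (n_samples, n_slices, ...) image stacks")
    n, n_slices = X.shape[0], X.shape[1]
    image_shape = X.shape[2:]
    X = X.reshape(n, n_slices, -1)
    if scope == "combined":
        blocks = [ImagePCA(k_max, random_state).fit(X.reshape(n, -1))]
    elif scope == "per-slice":
        blocks = [ImagePCA(k_max, random_state).fit(X[:, s, :]) for s in range(n_slices)]
    else:
        raise ValueError(f"scope must be 'per-slice' or 'combined', got {scope!r}")
    return ImageBasis(scope=scope, blocks=blocks, image_shape=tuple(image_shape),
                      n_slices=n_slices)


def project(images: np.ndarray, basis: ImageBasis, k: int | None = None) -> np.ndarray:
    """Functional alias for :meth:`ImageBasis.project`."""
    return basis.project(images, k=k)


# ---------------------------------------------------------------------------
# time basis


@dataclass(frozen=True)
class TimeBasis:
    """Cubic B-spline basis over cycle phase on uniform knots.

    The default is periodic (value and derivative continuity across the
    phase 0 == 1 wrap) with 8 basis functions; rows of the evaluated basis
    matrix sum to one (partition of unity), so the basis spans constants and
    no separate intercept is needed downstream.
    """

    n_basis: int = 8
    periodic: bool = True
    degree: int = 3

    def __post_init__(self) -> None:
        if self.n_basis < self.degree + 1:
            raise ValueError(f"n_basis must be at least degree+1={self.degree + 1}")


def evaluate_time_basis(phases: np.ndarray | Sequence[float],
                        basis: TimeBasis) -> np.ndarray:
    """Evaluate the spline basis at cycle phases; returns (n_obs, n_basis).

    Phases outside [0, 1) are wrapped modulo 1 (logged).
    """
    ph = np.atleast_1d(np.asarray(phases, dtype=float))
    if np.any((ph < 0.0) | (ph >= 1.0)):
        logger.info("phases outside [0, 1) wrapped modulo 1")
        ph = np.mod(ph, 1.0)
    n, k = basis.n_basis, basis.degree
    if basis.periodic:
        t = np.arange(-k, n + k + 1) / n
        D = BSpline.design_matrix(ph, t, k).toarray()  # (n_obs, n + k)
        out = D[:, :n].copy()
        out[:, :k] += D[:, n:]
        return out
    interior = np.linspace(0.0, 1.0, n - k + 1)
    t = np.concatenate([np.zeros(k), interior, np.ones(k)])
    return BSpline.design_matrix(ph, t, k).toarray()


class CyclicSplineFeatures(TransformerMixin, BaseEstimator):
    """sklearn-style transformer wrapping :func:`evaluate_time_basis`."""

    def __init__(self, n_basis: int = 8, periodic: bool = True):
        self.n_basis = n_basis
        self.periodic = periodic

    def fit(self, X, y=None) -> "CyclicSplineFeatures":
        self.basis_ = TimeBasis(n_basis=self.n_basis, periodic=self.periodic)
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "basis_"):
            self.fit(X)
        return evaluate_time_basis(np.asarray(X, dtype=float).ravel(), self.basis_)
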