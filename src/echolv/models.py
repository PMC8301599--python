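"""The three least-squares boundary-prediction model variants.

For each of the 48 anchor points the radius over the cycle is modelled as a
linear function of (a) principal-component scores of the short-axis images
and (b) a periodic cubic B-spline basis in cycle phase:

* **variant 1** -- scores of the target anchor's own slice only
  (one PCA subspace per slice level);
* **variant 2** -- scores of all four slices combined in one joint PCA
  subspace;
* **variant 3** -- variant 2 plus a single extra scalar parameter weighting a
  user-supplied *assist* annotation: the true radius of one chosen anchor at
  end-diastole for each dataset.  Because hearts differ mostly by size, that
  single number resolves each animal's size offset.

All 48 fits are independent ordinary-least-squares problems (minimum-norm
solutions when the design is rank deficient).  No intercept column is used:
the spline basis is a partition of unity and therefore spans constants.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from . import geometry
from .exceptions import MissingAnnotationError
from .features import ImageBasis, TimeBasis, evaluate_time_basis, fit_image_basis

logger = logging.getLogger(__name__)

#: default assist annotation site: endocardial anterior mid-ventricle
DEFAULT_ASSIST_ANCHOR = geometry.AnchorIndex(90.0, "endo", 0.50)


def assemble_design(scores: np.ndarray, phi: np.ndarray,
                    assist: np.ndarray | None = None) -> np.ndarray:
    """Stack the regressor blocks: ``[scores | spline basis (| assist column)]``."""
    scores = np.asarray(scores, dtype=float)
    blocks = [scores, np.asarray(phi, dtype=float)]
    if assist is not None:
        blocks.append(np.asarray(assist, dtype=float).reshape(-1, 1))
    return np.hstack(blocks)


def _as_stacks(X: Sequence) -> list[geometry.SliceStack]:
    out = []
    for d in X:
        if isinstance(d, geometry.SliceStack):
            out.append(d)
        else:
            out.append(geometry.slice_stack(d))
    return out


def _lstsq(design: np.ndarray, Y: np.ndarray) -> np.ndarray:
    if design.shape[0] <= design.shape[1]:
        logger.warning(
            "design has %d rows for %d columns; using the minimum-norm solution",
            design.shape[0], design.shape[1],
        )
    coef, _, rank, _ = np.linalg.lstsq(design, Y, rcond=None)
    if rank < design.shape[1]:
        logger.warning("rank-deficient design (rank %d < %d columns); "
                       "pseudoinverse solution used", rank, design.shape[1])
    return coef


class BoundaryRegressor(RegressorMixin, BaseEstimator):
    """Predict anchor radii from short-axis cine images.

    Parameters
    ----------
    variant : {1, 2, 3}
        Model variant (see module docstring).
    n_components : int
        Number of principal components k (shared across all 48 anchors;
        clipped to the feasible maximum with a warning).
    n_basis : int
        Number of periodic cubic B-spline basis functions over the cycle.
    assist_anchor : AnchorIndex
        Annotation site for variant 3 (default: endocardial, theta=90 deg,
        z=0.50).
    slice_fractions : tuple of float
        Apex-to-base fractions of the standard slices.

    Fitted attributes
    -----------------
    ``image_basis_`` (PCA basis), ``time_basis_``, ``coef_`` with one column
    per anchor (rows: k score weights *beta*, n_basis spline weights *gamma*,
    and for variant 3 the scalar assist weight *delta*), ``n_components_``.

    ``fit`` accepts lists of :class:`~echolv.phantom.CineDataset` or
    precomputed :class:`~echolv.geometry.SliceStack`; ``y`` is the matching
    list of :class:`~echolv.geometry.AnchorRadii`.  Rows are pooled over all
    training animals and frames.
    """

    def __init__(self, variant: int = 2, n_components: int = 8, n_basis: int = 8,
                 periodic_time_basis: bool = True,
                 assist_anchor: geometry.AnchorIndex = DEFAULT_ASSIST_ANCHOR,
                 slice_fractions: Sequence[float] = geometry.SLICE_FRACTIONS,
                 random_state: int = 0):
        self.variant = variant
        self.n_components = n_components
        self.n_basis = n_basis
        self.periodic_time_basis = periodic_time_basis
        self.assist_anchor = assist_anchor
        self.slice_fractions = slice_fractions
        self.random_state = random_state

    # -- helpers ----------------------------------------------------------

    @property
    def _scope(self) -> str:
        return "per-slice" if self.variant == 1 else "combined"

    def _assist_values(self, y: Sequence[geometry.AnchorRadii]) -> np.ndarray:
        """Per-dataset assist radius: the true value at the assist anchor at phase 0."""
        col = geometry.anchor_column(self.assist_anchor)
        return np.array([r.values[0, col] for r in y])

    def _slice_index_for(self, anchor: geometry.AnchorIndex) -> int:
        return list(self.slice_fractions).index(anchor.z_frac)

    # -- fitting ----------------------------------------------------------

    def fit(self, X: Sequence, y: Sequence[geometry.AnchorRadii],
            image_basis: ImageBasis | None = None) -> "BoundaryRegressor":
        """Fit all 48 anchor regressions on pooled (animal, frame) rows.

        ``image_basis`` may pass a basis already fitted on exactly these
        training images (used by the cross-validation harness to share the
        decomposition between variants 2 and 3); it is never fitted here on
        anything but training data.
        """
        if self.variant not in (1, 2, 3):
            raise ValueError(f"variant must be 1, 2 or 3, got {self.variant}")
        stacks = _as_stacks(X)
        if len(stacks) != len(y) or not stacks:
            raise ValueError("X and y must be equal-length, non-empty sequences")

        images = np.concatenate([s.images for s in stacks], axis=0)
        phases = np.concatenate([s.cycle_phase for s in stacks])
        Y = np.vstack([r.values for r in y])

        if image_basis is None:
            image_basis = fit_image_basis(images, self.n_components,
                                          scope=self._scope,
                                          random_state=self.random_state)
        self.image_basis_ = image_basis
        self.n_components_ = min(int(self.n_components), image_basis.k_max)
        self.time_basis_ = TimeBasis(n_basis=self.n_basis,
                                     periodic=self.periodic_time_basis)

        scores = image_basis.project(images, k=self.n_components_)
        phi = evaluate_time_basis(phases, self.time_basis_)
        assist = None
        if self.variant == 3:
            per_animal = self._assist_values(y)
            assist = np.concatenate(
                [np.full(s.n_frames, mu) for s, mu in zip(stacks, per_animal)]
            )

        self.coef_ = np.empty(
            (scores.shape[-1] + phi.shape[1] + (1 if self.variant == 3 else 0),
             geometry.N_ANCHORS)
        )
        if self.variant == 1:
            anchors = geometry.anchor_grid()
            for s_idx in range(len(self.slice_fractions)):
                cols = [j for j, a in enumerate(anchors)
                        if self._slice_index_for(a) == s_idx]
                design = assemble_design(scores[:, s_idx, :], phi)
                self.coef_[:, cols] = _lstsq(design, Y[:, cols])
        else:
            design = assemble_design(scores, phi, assist)
            self.coef_[:] = _lstsq(design, Y)

        # cache for cheap refits at truncated k (cross-validation k-selection)
        self._cache = {"scores": scores, "phi": phi, "Y": Y, "assist": assist}
        self.n_features_in_ = int(np.prod(images.shape[1:]))
        return self

    def with_components(self, k: int) -> "BoundaryRegressor":
        """Refit the linear coefficients using only the first ``k`` components.

        Reuses the fitted image basis and cached training blocks; equivalent
        to a full refit at ``n_components=k`` on the same training data.
        """
        if not hasattr(self, "_cache"):
            raise RuntimeError("with_components requires a model fitted in this session")
        if k > self.n_components_:
            raise ValueError(f"k={k} exceeds the fitted component count {self.n_components_}")
        out = BoundaryRegressor(**self.get_params())
        out.n_components = k
        out.image_basis_ = self.image_basis_
        out.n_components_ = k
        out.time_basis_ = self.time_basis_
        scores, phi = self._cache["scores"], self._cache["phi"]
        Y, assist = self._cache["Y"], self._cache["assist"]
        trunc = scores[..., :k]
        out.coef_ = np.empty(
            (k + phi.shape[1] + (1 if self.variant == 3 else 0), geometry.N_ANCHORS)
        )
        if self.variant == 1:
            anchors = geometry.anchor_grid()
            for s_idx in range(len(self.slice_fractions)):
                cols = [j for j, a in enumerate(anchors)
                        if self._slice_index_for(a) == s_idx]
                out.coef_[:, cols] = _lstsq(assemble_design(trunc[:, s_idx, :], phi),
                                            Y[:, cols])
        else:
            out.coef_[:] = _lstsq(assemble_design(trunc, phi, assist), Y)
        out._cache = {"scores": trunc, "phi": phi, "Y": Y, "assist": assist}
        out.n_features_in_ = self.n_features_in_
        return out

    # -- prediction -------------------------------------------------------

    def _predict_one(self, stack: geometry.SliceStack,
                     assist_value: float | None) -> geometry.AnchorRadii:
        scores = self.image_basis_.project(stack.images, k=self.n_components_)
        phi = evaluate_time_basis(stack.cycle_phase, self.time_basis_)
        if self.variant == 3:
            if assist_value is None:
                raise MissingAnnotationError(
                    "variant 3 requires the end-diastolic radius at the assist "
                    f"anchor {self.assist_anchor} for each dataset"
                )
            assist = np.full(stack.n_frames, float(assist_value))
        else:
            assist = None
        values = np.empty((stack.n_frames, geometry.N_ANCHORS))
        if self.variant == 1:
            anchors = geometry.anchor_grid()
            for s_idx in range(len(self.slice_fractions)):
                cols = [j for j, a in enumerate(anchors)
                        if self._slice_index_for(a) == s_idx]
                design = assemble_design(scores[:, s_idx, :], phi)
                values[:, cols] = design @ self.coef_[:, cols]
        else:
            design = assemble_design(scores, phi, assist)
            values[:] = design @ self.coef_
        return geometry.AnchorRadii(values=values, cycle_phase=stack.cycle_phase,
                                    validate=False)

    def predict(self, X: Sequence,
                assist_values: Sequence[float] | float | None = None
                ) -> list[geometry.AnchorRadii]:
        """Predict anchor radii for each dataset in ``X``.

        For variant 3 ``assist_values`` supplies the user annotation (one
        radius in mm per dataset, or a scalar when ``X`` has one element).
        """
        if not hasattr(self, "coef_"):
            raise RuntimeError("predict called before fit")
        stacks = _as_stacks(X)
        if assist_values is None:
            assist_list = [None] * len(stacks)
        elif np.isscalar(assist_values):
            assist_list = [float(assist_values)] * len(stacks)
        else:
            assist_list = [float(a) for a in assist_values]
            if len(assist_list) != len(stacks):
                raise MissingAnnotationError(
                    "one assist value is required per dataset"
                )
        return [self._predict_one(s, a) for s, a in zip(stacks, assist_list)]

    def score(self, X: Sequence, y: Sequence[geometry.AnchorRadii],
              assist_values: Sequence[float] | None = None) -> float:
        """Pooled R^2 over all anchors and (animal, frame) observations."""
        preds = self.predict(X, assist_values=assist_values)
        Y = np.vstack([r.values for r in y])
        P = np.vstack([p.values for p in preds])
        sse = float(np.sum((Y - P) ** 2))
        sst = float(np.sum((Y - Y.mean(axis=0)) ** 2))
        return 1.0 - sse / sst if sst > 0 else 0.0


# ---------------------------------------------------------------------------
# functional wrappers


def fit_boundary_model(X: Sequence, y: Sequence[geometry.AnchorRadii],
                       variant: int = 2, k: int = 8,
                       time_basis: TimeBasis | None = None,
                       assist_anchor: geometry.AnchorIndex = DEFAULT_ASSIST_ANCHOR,
                       ) -> BoundaryRegressor:
    """Fit a :class:`BoundaryRegressor`; thin functional wrapper."""
    tb = time_basis or TimeBasis()
    return BoundaryRegressor(
        variant=variant, n_components=k, n_basis=tb.n_basis,
        periodic_time_basis=tb.periodic, assist_anchor=assist_anchor,
    ).fit(X, y)


def predict_radii(model: BoundaryRegressor, dataset,
                  assist_value: float | None = None) -> geometry.AnchorRadii:
    """Predict the 48 anchor radii for a single dataset."""
    return model.predict([dataset], assist_values=assist_value)[0]
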