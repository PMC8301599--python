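"""Monte Carlo cross-validation harness and model-comparison statistics.

The cohort is repeatedly partitioned into train/validation/test sets at a
6:1:1 ratio (whole animals per split; no frame leakage).  For each iteration
and model variant the PCA basis and regression coefficients are fitted on
the training animals only, the validation set selects the number of
principal components k (smallest k on ties), and per-anchor mean squared
error (mm^2) and R^2 are evaluated on the held-out test set.

Model comparison uses paired two-sided t-tests on per-observation squared
errors within each (iteration, anchor) cell; "A significantly better than B"
means p < 0.05 *and* mean squared error of A below B.  The fraction of
significant cells aggregated over anchors and iterations is the
percent-significant statistic.  Ground-truth vs predicted metric tables are
compared per metric with paired t-tests under a Bonferroni correction
(adjusted p = min(1, p * n_metrics), flagged when adjusted p < 0.001).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import geometry
from .exceptions import InsufficientDataError, PairingError
from .models import DEFAULT_ASSIST_ANCHOR, BoundaryRegressor

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# partitioning


def mc_partition(animal_ids: Sequence[str], seed: int | None = None,
                 rng: np.random.Generator | None = None
                 ) -> tuple[list[str], list[str], list[str]]:
    """Random 6:1:1 train/validation/test split over whole animals.

    Validation and test each receive ``floor(n / 8)`` animals; the remainder
    goes to training.  Requires at least 8 animals.  Deterministic for a
    fixed seed.
    """
    ids = list(animal_ids)
    n = len(ids)
    if n < 8:
        raise InsufficientDataError(f"Monte Carlo splitting needs >= 8 animals, got {n}")
    if rng is None:
        rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_small = n // 8
    test = sorted(ids[i] for i in perm[:n_small])
    val = sorted(ids[i] for i in perm[n_small:2 * n_small])
    train = sorted(ids[i] for i in perm[2 * n_small:])
    return train, val, test


# ---------------------------------------------------------------------------
# paired tests


def paired_error_ttest(errors_a: np.ndarray, errors_b: np.ndarray) -> dict[str, float]:
    """Paired two-sided t-test on per-observation squared-error differences.

    Returns ``{"t", "p", "mean_diff", "degenerate"}``.  For zero-variance
    differences the p-value is reported as exactly 0 when the mean difference
    is non-zero (the difference is then deterministic) and 1 otherwise, with
    the degenerate flag set.
    """
    a = np.asarray(errors_a, dtype=float)
    b = np.asarray(errors_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be equal-length 1D arrays")
    n = a.size
    if n < 3:
        raise InsufficientDataError(f"paired t-test needs n >= 3, got {n}")
    d = a - b
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        return {"t": float(np.sign(mean)) * np.inf if mean != 0 else 0.0,
                "p": 0.0 if mean != 0 else 1.0,
                "mean_diff": mean, "degenerate": True}
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * float(stats.t.sf(abs(t), df=n - 1))
    return {"t": float(t), "p": p, "mean_diff": mean, "degenerate": False}


def significantly_better(errors_a: np.ndarray, errors_b: np.ndarray,
                         alpha: float = 0.05) -> bool:
    """True when A's squared errors are significantly below B's."""
    res = paired_error_ttest(errors_a, errors_b)
    return res["p"] < alpha and float(np.mean(errors_a)) < float(np.mean(errors_b))


# ---------------------------------------------------------------------------
# cross-validation


@dataclass
class IterationResult:
    """One Monte Carlo iteration: split, selected k and per-anchor test scores."""

    train_ids: list[str]
    val_ids: list[str]
    test_ids: list[str]
    selected_k: dict[int, int]
    mse: dict[int, np.ndarray]  # variant -> (48,) mm^2
    r2: dict[int, np.ndarray]  # variant -> (48,)
    sq_errors: dict[int, np.ndarray] = field(repr=False, default_factory=dict)
    # variant -> (n_test_obs, 48) per-observation squared errors


@dataclass
class CVResult:
    """Aggregated Monte Carlo cross-validation output."""

    iterations: list[IterationResult]
    variants: tuple[int, ...]
    k_grid: tuple[int, ...]
    seed: int

    # -- aggregates -------------------------------------------------------

    def _stack(self, variant: int, stat: str) -> np.ndarray:
        return np.stack([getattr(it, stat)[variant] for it in self.iterations])

    def median_grid(self, variant: int, boundary: str,
                    stat: str = "mse") -> pd.DataFrame:
        """Median (over iterations) per-anchor statistic as a theta x z grid."""
        med = np.median(self._stack(variant, stat), axis=0)
        grid = med.reshape(4, 2, 6)[:, geometry.BOUNDARIES.index(boundary), :]
        return pd.DataFrame(
            grid.T,
            index=pd.Index(geometry.ANCHOR_THETAS_DEG, name="theta_deg"),
            columns=pd.Index(geometry.ANCHOR_Z_FRACS, name="z_frac"),
        )

    def boundary_summary(self) -> pd.DataFrame:
        """Mean +/- SD test MSE and mean R^2 per variant and boundary.

        The per-iteration, per-boundary MSE is the mean over that boundary's
        24 anchors; mean and SD are then taken across iterations.
        """
        rows = []
        sel = np.array([a.boundary == "endo" for a in geometry.anchor_grid()])
        for variant in self.variants:
            mse = self._stack(variant, "mse")
            r2 = self._stack(variant, "r2")
            for bname, mask in (("endo", sel), ("epi", ~sel)):
                per_iter = mse[:, mask].mean(axis=1)
                rows.append({
                    "variant": variant, "boundary": bname,
                    "mse_mean": per_iter.mean(), "mse_sd": per_iter.std(ddof=1),
                    "r2_mean": r2[:, mask].mean(),
                })
        return pd.DataFrame(rows)

    def percent_significant(self, alpha: float = 0.05) -> pd.DataFrame:
        """Percent of (iteration, anchor) cells where the row model is
        significantly better than the column model, per boundary."""
        rows = []
        anchors = geometry.anchor_grid()
        for va in self.variants:
            for vb in self.variants:
                if va == vb:
                    continue
                counts = {"endo": [0, 0], "epi": [0, 0]}
                for it in self.iterations:
                    ea, eb = it.sq_errors[va], it.sq_errors[vb]
                    for j, a in enumerate(anchors):
                        counts[a.boundary][1] += 1
                        if significantly_better(ea[:, j], eb[:, j], alpha):
                            counts[a.boundary][0] += 1
                for bname, (hit, tot) in counts.items():
                    rows.append({"better": va, "worse": vb, "boundary": bname,
                                 "percent": 100.0 * hit / tot if tot else np.nan})
        return pd.DataFrame(rows)

    def ordering_fraction(self, order: Sequence[int] = (3, 2, 1),
                          stat: str = "mean") -> float:
        """Fraction of iterations whose per-iteration test MSE is monotone
        along ``order`` (first entry best).

        The per-iteration MSE aggregates the 48 anchors with ``stat``
        ("mean" by default, matching the per-boundary summary definition;
        "median" is more forgiving to variants with a few weak anchors).
        """
        agg = np.mean if stat == "mean" else np.median
        per_iter = {v: agg(self._stack(v, "mse"), axis=1) for v in order}
        ok = np.ones(len(self.iterations), dtype=bool)
        for better, worse in zip(order[:-1], order[1:]):
            ok &= per_iter[better] <= per_iter[worse]
        return float(ok.mean())

    def anchor_frame(self) -> pd.DataFrame:
        """Tidy anchor-level MSE/R^2 across iterations and variants."""
        anchors = geometry.anchor_grid()
        rows = []
        for i, it in enumerate(self.iterations):
            for v in self.variants:
                for j, a in enumerate(anchors):
                    rows.append({
                        "iteration": i, "variant": v, "theta_deg": a.theta_deg,
                        "boundary": a.boundary, "z_frac": a.z_frac,
                        "selected_k": it.selected_k[v],
                        "mse": it.mse[v][j], "r2": it.r2[v][j],
                    })
        return pd.DataFrame(rows)

    def to_json(self, path) -> None:
        payload = {
            "variants": list(self.variants),
            "k_grid": list(self.k_grid),
            "seed": self.seed,
            "iterations": [
                {
                    "train_ids": it.train_ids, "val_ids": it.val_ids,
                    "test_ids": it.test_ids,
                    "selected_k": {str(k): v for k, v in it.selected_k.items()},
                    "mse": {str(v): it.mse[v].tolist() for v in self.variants},
                    "r2": {str(v): it.r2[v].tolist() for v in self.variants},
                }
                for it in self.iterations
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _pooled_mse(preds: Sequence[geometry.AnchorRadii],
                truths: Sequence[geometry.AnchorRadii]) -> float:
    sq = [(p.values - t.values) ** 2 for p, t in zip(preds, truths)]
    return float(np.mean(np.vstack(sq)))


def run_cross_validation(
    cohort: Sequence[tuple],
    variants: Sequence[int] = (1, 2, 3),
    n_iter: int = 20,
    k_grid: Sequence[int] = (2, 4, 8, 12),
    seed: int = 0,
    n_basis: int = 8,
    assist_anchor: geometry.AnchorIndex = DEFAULT_ASSIST_ANCHOR,
) -> CVResult:
    """Monte Carlo cross-validation of the boundary models on a cohort.

    ``cohort`` is a sequence of ``(dataset, truth)`` pairs where ``dataset``
    is a :class:`~echolv.phantom.CineDataset` or precomputed
    :class:`~echolv.geometry.SliceStack` and ``truth`` the matching
    :class:`~echolv.geometry.AnchorRadii`.  Each iteration uses an
    independently seeded split (``seed + iteration``); PCA bases are refit
    inside every iteration on that iteration's training animals only, and
    variants 2 and 3 share the (identical) combined-scope basis.
    """
    if not k_grid:
        raise ValueError("k_grid must be non-empty")
    k_grid = tuple(sorted(int(k) for k in k_grid))
    stacks = [geometry.slice_stack(d) if not isinstance(d, geometry.SliceStack) else d
              for d, _ in cohort]
    truths = [t for _, t in cohort]
    ids = [s.animal_id for s in stacks]
    if len(set(ids)) != len(ids):
        raise ValueError("animal ids must be unique")
    by_id = {i: (s, t) for i, s, t in zip(ids, stacks, truths)}
    assist_col = geometry.anchor_column(assist_anchor)

    iterations = []
    for it in range(n_iter):
        train_ids, val_ids, test_ids = mc_partition(ids, seed=seed + it)
        tr_s = [by_id[i][0] for i in train_ids]
        tr_y = [by_id[i][1] for i in train_ids]
        va_s = [by_id[i][0] for i in val_ids]
        va_y = [by_id[i][1] for i in val_ids]
        te_s = [by_id[i][0] for i in test_ids]
        te_y = [by_id[i][1] for i in test_ids]
        va_assist = [y.values[0, assist_col] for y in va_y]
        te_assist = [y.values[0, assist_col] for y in te_y]

        selected_k: dict[int, int] = {}
        mse: dict[int, np.ndarray] = {}
        r2: dict[int, np.ndarray] = {}
        sq_errors: dict[int, np.ndarray] = {}
        shared_basis = None
        for variant in variants:
            model = BoundaryRegressor(
                variant=variant, n_components=max(k_grid), n_basis=n_basis,
                assist_anchor=assist_anchor,
            ).fit(tr_s, tr_y,
                  image_basis=shared_basis if variant in (2, 3) else None)
            if variant in (2, 3) and shared_basis is None:
                shared_basis = model.image_basis_

            best_k, best_mse, best_model = None, np.inf, None
            for k in k_grid:
                if k > model.n_components_:
                    logger.warning("k=%d exceeds feasible components (%d); skipped",
                                   k, model.n_components_)
                    continue
                mk = model.with_components(k)
                vmse = _pooled_mse(
                    mk.predict(va_s, assist_values=va_assist if variant == 3 else None),
                    va_y,
                )
                if vmse < best_mse:
                    best_k, best_mse, best_model = k, vmse, mk
            if best_model is None:
                raise InsufficientDataError("no feasible k in k_grid")
            selected_k[variant] = best_k

            preds = best_model.predict(
                te_s, assist_values=te_assist if variant == 3 else None
            )
            sq = np.vstack([(p.values - t.values) ** 2 for p, t in zip(preds, te_y)])
            truth = np.vstack([t.values for t in te_y])
            sse = sq.sum(axis=0)
            sst = ((truth - truth.mean(axis=0)) ** 2).sum(axis=0)
            mse[variant] = sq.mean(axis=0)
            r2[variant] = np.where(sst > 0, 1.0 - sse / np.where(sst > 0, sst, 1.0), 0.0)
            sq_errors[variant] = sq
        iterations.append(IterationResult(
            train_ids=train_ids, val_ids=val_ids, test_ids=test_ids,
            selected_k=selected_k, mse=mse, r2=r2, sq_errors=sq_errors,
        ))
    return CVResult(iterations=iterations, variants=tuple(variants),
                    k_grid=k_grid, seed=seed)


# ---------------------------------------------------------------------------
# metric-table comparison


def compare_metric_tables(truth_tables: Sequence[pd.DataFrame],
                          predicted_tables: Sequence[pd.DataFrame],
                          n_metrics: int | None = None,
                          alpha: float = 0.001) -> pd.DataFrame:
    """Paired t-tests (Bonferroni-corrected) of predicted vs truth metrics.

    One test per metric row across matched datasets; adjusted
    p = min(1, p * n_metrics); a metric is flagged when adjusted p < alpha.
    Degenerate (zero-variance, zero-mean) differences -- e.g. identical
    tables -- are never flagged.
    """
    if len(truth_tables) != len(predicted_tables) or len(truth_tables) < 3:
        raise PairingError("need >= 3 matched (truth, predicted) table pairs")
    keys = ["metric", "frame_type", "location", "boundary"]
    ref = truth_tables[0][keys]

    def values(tables: Sequence[pd.DataFrame]) -> np.ndarray:
        out = []
        for tab in tables:
            if len(tab) != len(ref) or not (tab[keys].values == ref.values).all():
                raise PairingError("metric tables are not aligned across datasets")
            out.append(tab["value"].to_numpy(dtype=float))
        return np.vstack(out)  # (n_datasets, n_metrics)

    T = values(truth_tables)
    P = values(predicted_tables)
    m = T.shape[1]
    if n_metrics is None:
        n_metrics = m
    rows = []
    for j in range(m):
        res = paired_error_ttest(P[:, j], T[:, j])
        p_adj = min(1.0, res["p"] * n_metrics)
        rows.append({
            **{k: ref.iloc[j][k] for k in keys},
            "t": res["t"], "p": res["p"], "p_adjusted": p_adj,
            "mean_diff": res["mean_diff"], "degenerate": res["degenerate"],
            "flagged": bool(p_adj < alpha and not (res["degenerate"]
                                                   and res["mean_diff"] == 0.0)),
        })
    return pd.DataFrame(rows)
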