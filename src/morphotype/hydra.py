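"""Semi-supervised max-margin polytope clustering (HYDRA-style).

The engine searches for ``k`` subtypes *within* the clinical group while
each subtype is separated from the full control group by its own
regularized linear max-margin hyperplane; the k hyperplanes form a convex
polytope around the controls. Clustering and classification are carried
out simultaneously by alternating optimization:

1. initialize clinical subtype assignments at random;
2. for each subtype j, fit a linear max-margin classifier separating all
   controls (negative class) from that subtype's clinical members
   (positive class), controls down-weighted by 1/k so the control class
   does not dominate any single face;
3. reassign every clinical subject to ``argmax_j (w_j . x + b_j)``;
4. repeat 2-3 until assignments stop changing or an iteration cap.

Stability against initialization comes from consensus over seeded
restarts: the co-assignment frequency matrix of the restarts is grouped by
average-linkage agglomeration, and the polytope is refit once from the
consensus labels.

Features are adjusted for nuisance covariates (least squares on the pooled
sample) and z-scored per ROI before fitting; margin methods are
scale-sensitive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.cluster import AgglomerativeClustering
from sklearn.svm import LinearSVC

from .datatypes import FeatureTable, SubjectRecord

__all__ = [
    "HydraConfig", "PolytopeModel", "ClusteringSolution",
    "adjust_covariates", "standardize_features", "fit_margin_classifier",
    "fit_polytope_once", "fit_hydra", "assign_new",
]

logger = logging.getLogger(__name__)


@dataclass
class HydraConfig:
    """Hyperparameters of the polytope fit.

    ``regularization`` is the margin-penalty weight C of each face's
    classifier; ``tolerance`` is the fraction of clinical subjects allowed
    to change assignment while still declaring convergence (0 demands an
    exact fixed point).
    """

    k: int = 2
    n_restarts: int = 20
    max_iterations: int = 50
    regularization: float = 0.25
    tolerance: float = 0.0
    seed: int = 0
    covariate_sample: str = "pooled"  # or "control" — who the adjustment is fit on

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        if self.regularization <= 0:
            raise ValueError("regularization must be positive")


@dataclass
class PolytopeModel:
    """k max-margin hyperplanes (one per subtype face) and the objective."""

    weights: np.ndarray      # (k, n_rois)
    intercepts: np.ndarray   # (k,)
    objective: float = float("nan")

    @property
    def k(self) -> int:
        return self.weights.shape[0]

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.weights.shape[1]:
            raise ValueError(
                f"feature dimension {X.shape[1]} does not match model "
                f"dimension {self.weights.shape[1]}")
        return X @ self.weights.T + self.intercepts[None, :]


@dataclass
class ClusteringSolution:
    """Final consensus subtype labels for the clinical subjects."""

    labels: dict[str, int]           # clinical subject id -> 1..k
    model: PolytopeModel
    coassignment: np.ndarray         # clinical x clinical frequency over restarts
    clinical_ids: list[str]
    converged: bool = True
    feature_mean: Optional[np.ndarray] = None   # training standardization
    feature_sd: Optional[np.ndarray] = None
    roi_ids: Optional[list[str]] = None

    def label_array(self) -> np.ndarray:
        return np.array([self.labels[s] for s in self.clinical_ids], dtype=int)

    def predict(self, features: FeatureTable) -> dict[str, int]:
        """Subtype of each (covariate-adjusted) subject under this model.

        Features are mapped into the training standardization before the
        polytope decision rule is applied.
        """
        if self.feature_mean is None:
            raise ValueError("solution lacks stored standardization parameters")
        if self.roi_ids is not None and features.roi_ids != self.roi_ids:
            raise ValueError("feature table ROIs do not match the fitted model")
        Z = (features.values - self.feature_mean) / self.feature_sd
        D = self.model.decision_values(Z)
        labels = np.argmax(D, axis=1) + 1
        return {s: int(l) for s, l in zip(features.subject_ids, labels)}


# ---------------------------------------------------------------------------
# preprocessing

def adjust_covariates(features: FeatureTable, records: Sequence[SubjectRecord],
                      covariate_names: Sequence[str] = ("age", "handedness"),
                      sample: str = "pooled") -> FeatureTable:
    """Remove per-ROI linear nuisance-covariate effects by least squares.

    Effects are estimated on the pooled sample by default (``sample=
    "control"`` estimates them on controls only and applies them to all).
    The returned residual table is mean-centered and, for a pooled fit,
    exactly orthogonal to every covariate per ROI.

    Constant covariates are dropped with a warning; a missing covariate
    value anywhere rejects the subject list.
    """
    rec_by_id = {r.subject_id: r for r in records}
    missing = [s for s in features.subject_ids if s not in rec_by_id]
    if missing:
        raise ValueError(f"no metadata for subjects: {missing[:5]}")
    cols = []
    kept = []
    for name in covariate_names:
        v = np.array([getattr(rec_by_id[s], name) for s in features.subject_ids],
                     dtype=float)
        if np.any(~np.isfinite(v)):
            raise ValueError(f"covariate {name!r} has missing values")
        if np.ptp(v) == 0:
            logger.warning("covariate %r is constant; dropping it", name)
            continue
        cols.append(v)
        kept.append(name)
    X = np.column_stack([np.ones(features.n_subjects)] + cols)
    Y = features.values
    if sample == "pooled":
        beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    elif sample == "control":
        ctrl = np.array([rec_by_id[s].group == "control" for s in features.subject_ids])
        if not ctrl.any():
            raise ValueError("control-only adjustment requires controls")
        beta, *_ = np.linalg.lstsq(X[ctrl], Y[ctrl], rcond=None)
    else:
        raise ValueError(f"unknown adjustment sample {sample!r}")
    return features.with_values(Y - X @ beta)


def standardize_features(values: np.ndarray) -> np.ndarray:
    """Per-ROI z-score over all subjects (zero-variance ROIs left centered)."""
    mu = values.mean(axis=0)
    sd = values.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (values - mu) / sd


# ---------------------------------------------------------------------------
# fitting

def fit_margin_classifier(X: np.ndarray, y: np.ndarray, C: float,
                          sample_weight: Optional[np.ndarray] = None
                          ) -> tuple[np.ndarray, float]:
    """One regularized linear max-margin face: returns (w, b).

    L2-regularized squared-hinge SVM solved in the primal (deterministic,
    no solver randomness). Decision value is ``w . x + b``, positive for
    the clinical class (y == 1).
    """
    clf = LinearSVC(C=C, loss="squared_hinge", penalty="l2", dual=False,
                    tol=1e-7, max_iter=20000)
    clf.fit(X, y, sample_weight=sample_weight)
    return clf.coef_[0].copy(), float(clf.intercept_[0])


def _face_objective(w: np.ndarray, b: float, X: np.ndarray, y_signed: np.ndarray,
                    sw: np.ndarray, C: float) -> float:
    margins = 1.0 - y_signed * (X @ w + b)
    hinge2 = np.square(np.maximum(margins, 0.0))
    return 0.5 * float(w @ w) + C * float(sw @ hinge2)


def polytope_objective(model: PolytopeModel, X: np.ndarray, is_clinical: np.ndarray,
                       labels: np.ndarray, C: float) -> float:
    """Sum of per-face regularized squared-hinge objectives.

    Each face separates all controls (weight 1/k) from its subtype's
    members (weight 1); subjects of other subtypes do not enter that face.
    """
    k = model.k
    total = 0.0
    Xc = X[~is_clinical]
    Xp = X[is_clinical]
    for j in range(k):
        members = labels == j + 1
        Xj = np.vstack([Xc, Xp[members]])
        yj = np.concatenate([-np.ones(len(Xc)), np.ones(members.sum())])
        swj = np.concatenate([np.full(len(Xc), 1.0 / k), np.ones(members.sum())])
        total += _face_objective(model.weights[j], model.intercepts[j], Xj, yj, swj, C)
    return total


def _fit_faces(X: np.ndarray, is_clinical: np.ndarray, labels: np.ndarray,
               k: int, C: float) -> PolytopeModel:
    n_rois = X.shape[1]
    Xc = X[~is_clinical]
    Xp = X[is_clinical]
    W = np.zeros((k, n_rois))
    b = np.zeros(k)
    for j in range(k):
        members = labels == j + 1
        nm = int(members.sum())
        Xj = np.vstack([Xc, Xp[members]])
        yj = np.concatenate([np.zeros(len(Xc)), np.ones(nm)])
        swj = np.concatenate([np.full(len(Xc), 1.0 / k), np.ones(nm)])
        W[j], b[j] = fit_margin_classifier(Xj, yj, C, swj)
    model = PolytopeModel(W, b)
    model.objective = polytope_objective(model, X, is_clinical, labels, C)
    return model


def fit_polytope_once(features_adjusted: np.ndarray, group_labels: np.ndarray,
                      k: int, config: HydraConfig, restart_seed: int
                      ) -> tuple[np.ndarray, PolytopeModel, bool]:
    """One alternating-optimization run from a random initialization.

    Parameters
    ----------
    features_adjusted
        Subjects x ROIs matrix, covariate-adjusted and standardized.
    group_labels
        Boolean per subject, True for clinical.
    restart_seed
        Seeds the random initial assignment; identical seeds give
        identical runs.

    Returns ``(labels, model, converged)`` with labels in 1..k over the
    clinical subjects in row order.
    """
    X = np.asarray(features_adjusted, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite features")
    is_clinical = np.asarray(group_labels, dtype=bool)
    n_clin = int(is_clinical.sum())
    if n_clin < k:
        raise ValueError(f"k={k} exceeds the {n_clin} clinical subjects")
    if n_clin == is_clinical.size:
        raise ValueError("control group is empty")

    rng = np.random.default_rng(restart_seed)
    # diversity-promoting random exemplar initialization (k-means++-style
    # D^2 sampling over clinical subjects, nearest-exemplar assignment).
    # A spatially coherent, spread-out start lets the first face fits
    # differentiate; purely random label draws almost always converge to
    # poor self-consistent fixed points.
    Xp = X[is_clinical]
    exemplars = [int(rng.integers(n_clin))]
    for _ in range(k - 1):
        d2 = np.min(((Xp[:, None, :] - Xp[exemplars][None, :, :]) ** 2
                     ).sum(axis=-1), axis=1)
        total = d2.sum()
        if total <= 0:  # all duplicates: fall back to uniform choice
            exemplars.append(int(rng.integers(n_clin)))
        else:
            exemplars.append(int(rng.choice(n_clin, p=d2 / total)))
    d2 = ((Xp[:, None, :] - Xp[np.array(exemplars)][None, :, :]) ** 2).sum(axis=-1)
    labels = np.argmin(d2, axis=1) + 1
    for j in range(1, k + 1):  # guarantee a non-degenerate start
        if not np.any(labels == j):
            labels[exemplars[j - 1]] = j

    converged = False
    model = None
    tol_changes = int(np.floor(config.tolerance * n_clin))
    for _ in range(config.max_iterations):
        model = _fit_faces(X, is_clinical, labels, k, config.regularization)
        D = model.decision_values(X[is_clinical])
        new_labels = np.argmax(D, axis=1) + 1      # ties -> lowest index
        # reseed empty subtypes with the least-polytope-like subject whose
        # move does not empty another subtype
        order = np.argsort(D.max(axis=1), kind="stable")
        while True:
            counts = np.bincount(new_labels, minlength=k + 1)[1:]
            empty = np.where(counts == 0)[0]
            if empty.size == 0:
                break
            j = int(empty[0]) + 1
            pick = next(int(i) for i in order
                        if counts[new_labels[i] - 1] > 1)
            new_labels[pick] = j
        changes = int(np.sum(new_labels != labels))
        labels = new_labels
        if changes <= tol_changes:
            converged = True
            break
    assert model is not None
    model.objective = polytope_objective(model, X, is_clinical, labels,
                                         config.regularization)
    return labels, model, converged


def fit_hydra(features: FeatureTable, records: Sequence[SubjectRecord],
              k: Optional[int] = None, config: Optional[HydraConfig] = None,
              covariate_names: Sequence[str] = ("age", "handedness"),
              preadjusted: bool = False) -> ClusteringSolution:
    """Consensus polytope clustering of the clinical group.

    Runs :func:`fit_polytope_once` for ``config.n_restarts`` seeded
    restarts, accumulates the clinical co-assignment frequency matrix,
    groups it by average-linkage agglomeration on distance
    ``1 - coassignment``, and refits the polytope once from the consensus
    labels.

    Set ``preadjusted=True`` when the features have already been
    covariate-adjusted (they are standardized here either way).
    """
    config = config or HydraConfig()
    if k is not None:
        config = HydraConfig(**{**config.__dict__, "k": k})
    k = config.k

    rec_by_id = {r.subject_id: r for r in records}
    groups = np.array([rec_by_id[s].group == "clinical" for s in features.subject_ids])
    clinical_ids = [s for s in features.subject_ids if rec_by_id[s].group == "clinical"]

    if not preadjusted:
        features = adjust_covariates(features, records, covariate_names,
                                     sample=config.covariate_sample)
    mu = features.values.mean(axis=0)
    sd = features.values.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    X = (features.values - mu) / sd

    n_clin = len(clinical_ids)
    seeds = np.random.SeedSequence(config.seed).generate_state(config.n_restarts + 1)
    co = np.zeros((n_clin, n_clin))
    all_converged = True
    for r in range(config.n_restarts):
        lab, _, conv = fit_polytope_once(X, groups, k, config, int(seeds[r] % 2**31))
        all_converged &= conv
        co += (lab[:, None] == lab[None, :])
    co /= config.n_restarts

    if k == 1 or n_clin == 1:
        consensus = np.ones(n_clin, dtype=int)
    else:
        agg = AgglomerativeClustering(n_clusters=k, metric="precomputed",
                                      linkage="average")
        grouping = agg.fit_predict(1.0 - co)
        # stable relabel: subtype 1 = group of the first clinical subject, etc.
        consensus = np.zeros(n_clin, dtype=int)
        next_label = 1
        for g in grouping:  # first-appearance order
            if not np.any(consensus[grouping == g]):
                consensus[grouping == g] = next_label
                next_label += 1
    model = _fit_faces(X, groups, consensus, k, config.regularization)

    return ClusteringSolution(
        labels={clinical_ids[i]: int(consensus[i]) for i in range(n_clin)},
        model=model, coassignment=co, clinical_ids=clinical_ids,
        converged=all_converged, feature_mean=mu, feature_sd=sd,
        roi_ids=list(features.roi_ids))


def assign_new(model: PolytopeModel, features_row: np.ndarray) -> int:
    """Subtype of a new (standardized-space) feature vector.

    ``argmax_j (w_j . x + b_j)``; ties break to the lowest subtype index.
    """
    d = model.decision_values(np.atleast_2d(features_row))[0]
    return int(np.argmax(d)) + 1
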