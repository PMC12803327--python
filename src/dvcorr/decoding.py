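"""Decode per-trial decision variables (DVs) from a representation.

For each pair of classes the representation is treated as the input to an
optimal linear readout: the pair's trials are reduced by PCA to a common
dimensionality k, then a two-class Fisher discriminant supplies the decision
axis, and each trial's signed projection onto that axis is its decision
variable. The same reduction with held-out evaluation yields binary choices
(cross-validated logistic regression) and classification accuracies
(cross-validated LDA sign rule).

The DV decoder is deliberately fit in-sample — the DV is a description of
the representation's task-relevant axis, not a generalization claim —
whereas choices and accuracies are always cross-validated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.covariance import ledoit_wolf_shrinkage
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .data import ClassPair, Representation, StimulusSet

__all__ = [
    "DecisionAxis",
    "DVSeries",
    "ChoiceSeries",
    "fit_pca",
    "fit_lda_axis",
    "decode_dv",
    "decode_choices_cv",
    "classification_accuracy",
    "default_k",
]

#: cap on the default reduced dimensionality; LDA is unstable when the
#: trial count per retained dimension gets small
DEFAULT_MAX_K = 50

#: pooled-covariance condition number beyond which shrinkage kicks in
CONDITION_THRESHOLD = 1e6


@dataclass
class DecisionAxis:
    """A fitted PCA basis plus LDA axis for one class pair."""

    class_pair: ClassPair
    pca_basis: np.ndarray  # features x k, orthonormal columns
    pca_center: np.ndarray
    lda_weights: np.ndarray  # length k, unit norm
    lda_offset: float
    k: int

    def project(self, matrix: np.ndarray) -> np.ndarray:
        z = (np.asarray(matrix, float) - self.pca_center) @ self.pca_basis
        return z @ self.lda_weights - self.lda_offset


@dataclass
class DVSeries:
    """Per-trial scalar decision variables for one observer and class pair.

    ``sign_convention`` names the class whose trials project positive on
    average (always the lexicographically later class of the pair).
    """

    observer_id: str
    class_pair: ClassPair
    stimulus_id: np.ndarray
    dv: np.ndarray
    trial_classes: np.ndarray
    sign_convention: str

    def __post_init__(self) -> None:
        self.stimulus_id = np.asarray(self.stimulus_id, dtype=str)
        self.dv = np.asarray(self.dv, dtype=float)
        self.trial_classes = np.asarray(self.trial_classes, dtype=str)
        if not (self.stimulus_id.size == self.dv.size == self.trial_classes.size):
            raise ValueError("DVSeries fields must have equal length")
        if not np.isfinite(self.dv).all():
            raise ValueError("DVSeries contains non-finite values")

    def __len__(self) -> int:
        return int(self.dv.size)

    def class_mask(self, label: str) -> np.ndarray:
        return self.trial_classes == label

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "observer_id": self.observer_id,
                "stimulus_id": self.stimulus_id,
                "class_pair": str(self.class_pair),
                "true_class": self.trial_classes,
                "dv": self.dv,
            }
        )


@dataclass
class ChoiceSeries:
    """Per-trial binary choices (class labels) for one observer and class pair."""

    observer_id: str
    class_pair: ClassPair
    stimulus_id: np.ndarray
    choice: np.ndarray
    trial_classes: np.ndarray

    def __post_init__(self) -> None:
        self.stimulus_id = np.asarray(self.stimulus_id, dtype=str)
        self.choice = np.asarray(self.choice, dtype=str)
        self.trial_classes = np.asarray(self.trial_classes, dtype=str)
        if not (self.stimulus_id.size == self.choice.size == self.trial_classes.size):
            raise ValueError("ChoiceSeries fields must have equal length")
        extra = set(np.unique(self.choice)) - set(self.class_pair.classes)
        if extra:
            raise ValueError(f"choices outside the class pair: {sorted(extra)}")

    def __len__(self) -> int:
        return int(self.choice.size)

    @property
    def accuracy(self) -> float:
        return float(np.mean(self.choice == self.trial_classes))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "observer_id": self.observer_id,
                "stimulus_id": self.stimulus_id,
                "class_pair": str(self.class_pair),
                "true_class": self.trial_classes,
                "choice": self.choice,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ChoiceSeries":
        pairs = df["class_pair"].unique()
        if len(pairs) != 1:
            raise ValueError("choice table must contain a single class pair")
        return cls(
            observer_id=str(df["observer_id"].iloc[0]),
            class_pair=ClassPair.from_string(str(pairs[0])),
            stimulus_id=df["stimulus_id"].to_numpy(dtype=str),
            choice=df["choice"].to_numpy(dtype=str),
            trial_classes=df["true_class"].to_numpy(dtype=str),
        )


# ---------------------------------------------------------------------------
# PCA


def _centered_svd(matrix: np.ndarray):
    X = np.asarray(matrix, dtype=float)
    center = X.mean(axis=0)
    Xc = X - center
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    tol = max(X.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    rank = int((s > tol).sum())
    return center, U, s, Vt, rank


def _fix_signs(basis: np.ndarray) -> np.ndarray:
    # convention: each component's largest-magnitude loading is positive,
    # which makes the decomposition bit-stable across runs
    idx = np.abs(basis).argmax(axis=0)
    signs = np.sign(basis[idx, np.arange(basis.shape[1])])
    signs[signs == 0] = 1.0
    return basis * signs


def fit_pca(matrix: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Top-k principal components of the mean-centered matrix.

    Returns ``(basis, center)`` with ``basis`` a features x k matrix of
    orthonormal columns ordered by decreasing explained variance.
    Deterministic: each component's largest-magnitude loading is positive.
    """
    center, _, s, Vt, rank = _centered_svd(matrix)
    if rank == 0:
        raise ValueError("matrix has rank 0 (all trials identical); cannot fit PCA")
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > rank:
        raise ValueError(
            f"k={k} exceeds the matrix rank; maximum achievable k is {rank}"
        )
    basis = _fix_signs(Vt[:k].T.copy())
    return basis, center


def default_k(n_trials: int, rank: int) -> int:
    """Shared data-limited default dimensionality for a pair comparison."""
    return max(1, min(DEFAULT_MAX_K, n_trials // 10, rank))


# ---------------------------------------------------------------------------
# LDA


def fit_lda_axis(
    reduced: np.ndarray, labels: np.ndarray
) -> tuple[np.ndarray, float]:
    """Two-class Fisher discriminant axis on reduced data.

    ``labels`` is boolean (True = positive class). Weights are proportional
    to pooled-within-class-covariance^-1 (mean_pos - mean_neg), normalized
    to unit Euclidean norm; the offset places the midpoint of the projected
    class means at zero. When the pooled covariance is ill-conditioned
    (condition number > 1e6) it is blended with (trace/k) * I at a
    Ledoit-Wolf analytic shrinkage intensity.
    """
    X = np.atleast_2d(np.asarray(reduced, dtype=float))
    y = np.asarray(labels, dtype=bool)
    if X.shape[0] != y.size:
        raise ValueError("reduced matrix and labels disagree in length")
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos < 2 or n_neg < 2:
        raise ValueError("each class needs >= 2 trials to fit an LDA axis")
    mu_neg = X[~y].mean(axis=0)
    mu_pos = X[y].mean(axis=0)
    Xw = np.vstack([X[~y] - mu_neg, X[y] - mu_pos])
    k = X.shape[1]
    S = (Xw.T @ Xw) / (X.shape[0] - 2)
    tr = np.trace(S)
    if tr <= 0:
        raise ValueError("all trials identical within classes; LDA axis undefined")
    with np.errstate(all="ignore"):
        cond = np.linalg.cond(S)
    if not np.isfinite(cond) or cond > CONDITION_THRESHOLD:
        lam = max(float(ledoit_wolf_shrinkage(Xw, assume_centered=True)), 1e-4)
        S = (1.0 - lam) * S + lam * (tr / k) * np.eye(k)
    delta = mu_pos - mu_neg
    norm_delta = np.linalg.norm(delta)
    if norm_delta == 0:
        raise ValueError("class means coincide; LDA axis undefined")
    w = np.linalg.solve(S, delta)
    w = w / np.linalg.norm(w)
    offset = float(w @ (mu_neg + mu_pos) / 2.0)
    return w, offset


# ---------------------------------------------------------------------------
# DV decoding


def _pair_subset(
    rep: Representation,
    stim: StimulusSet,
    pair: ClassPair,
    feature_subset: np.ndarray | None,
):
    rep.validate_against(stim)
    mask = stim.pair_mask(pair)
    X = rep.matrix[mask]
    if feature_subset is not None:
        feature_subset = np.asarray(feature_subset, dtype=int)
        if feature_subset.size == 0:
            raise ValueError("feature_subset must be nonempty")
        X = X[:, feature_subset]
    labels = stim.class_label[mask]
    ids = stim.stimulus_id[mask]
    return X, labels, ids


def fit_decision_axis(
    rep: Representation,
    stim: StimulusSet,
    pair: ClassPair,
    k: int | None = None,
    feature_subset: np.ndarray | None = None,
) -> DecisionAxis:
    """PCA + LDA fit on a pair's trials; returns the reusable axis."""
    X, labels, _ = _pair_subset(rep, stim, pair, feature_subset)
    center, _, _, Vt, rank = _centered_svd(X)
    if rank == 0:
        raise ValueError("matrix has rank 0 (all trials identical); cannot fit PCA")
    if k is None:
        k_eff = default_k(X.shape[0], rank)
    else:
        if k > rank:
            raise ValueError(
                f"k={k} exceeds the matrix rank; maximum achievable k is {rank}"
            )
        k_eff = int(k)
    basis = _fix_signs(Vt[:k_eff].T.copy())
    Z = (X - center) @ basis
    y = labels == pair.class_b
    w, offset = fit_lda_axis(Z, y)
    # w points from class_a toward class_b by construction (positive definite
    # covariance); keep an explicit guard for degenerate shrinkage cases
    if (Z[y] @ w).mean() < (Z[~y] @ w).mean():
        w, offset = -w, -offset
    return DecisionAxis(
        class_pair=pair,
        pca_basis=basis,
        pca_center=center,
        lda_weights=w,
        lda_offset=offset,
        k=k_eff,
    )


def decode_dv(
    rep: Representation,
    stim: StimulusSet,
    pair: ClassPair,
    k: int | None = None,
    feature_subset: np.ndarray | None = None,
) -> DVSeries:
    """Decision variables for one observer and class pair.

    Restricts to the pair's trials (and to ``feature_subset`` if given),
    fits PCA then LDA on those trials, and returns signed projections with
    the axis midpoint subtracted. Trials of ``pair.class_b`` project
    positive on average.
    """
    axis = fit_decision_axis(rep, stim, pair, k=k, feature_subset=feature_subset)
    X, labels, ids = _pair_subset(rep, stim, pair, feature_subset)
    dv = axis.project(X)
    return DVSeries(
        observer_id=rep.observer_id,
        class_pair=pair,
        stimulus_id=ids,
        dv=dv,
        trial_classes=labels,
        sign_convention=pair.class_b,
    )


# ---------------------------------------------------------------------------
# cross-validated choices and accuracy


def _check_folds(labels: np.ndarray, pair: ClassPair, n_folds: int) -> None:
    for cls in pair.classes:
        n = int((labels == cls).sum())
        if n < n_folds:
            raise ValueError(
                f"class {cls!r} has {n} trials, fewer than n_folds={n_folds}"
            )


def decode_choices_cv(
    rep: Representation,
    stim: StimulusSet,
    pair: ClassPair,
    k: int | None = None,
    n_folds: int = 5,
    seed: int = 0,
) -> ChoiceSeries:
    """Held-out binary choices from cross-validated logistic regression.

    Stratified ``n_folds``-fold split seeded by ``seed``; per fold, PCA and a
    logistic classifier are fit on the training trials and each held-out
    trial's choice is the sign of its predicted probability versus 0.5
    (ties break toward ``class_a``). Every trial receives exactly one
    held-out choice.
    """
    X, labels, ids = _pair_subset(rep, stim, pair, None)
    _check_folds(labels, pair, n_folds)
    y = labels == pair.class_b
    choices = np.empty(labels.size, dtype=object)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    for train, test in skf.split(X, y):
        center, _, _, Vt, rank = _centered_svd(X[train])
        k_eff = default_k(train.size, rank) if k is None else min(int(k), rank)
        basis = _fix_signs(Vt[:k_eff].T.copy())
        Ztr = (X[train] - center) @ basis
        Zte = (X[test] - center) @ basis
        clf = LogisticRegression(max_iter=1000)
        clf.fit(Ztr, y[train])
        pos_col = int(np.flatnonzero(clf.classes_)[0]) if clf.classes_.size == 2 else 0
        prob_b = clf.predict_proba(Zte)[:, pos_col]
        choices[test] = np.where(prob_b > 0.5, pair.class_b, pair.class_a)
    return ChoiceSeries(
        observer_id=rep.observer_id,
        class_pair=pair,
        stimulus_id=ids,
        choice=choices.astype(str),
        trial_classes=labels,
    )


def classification_accuracy(
    rep: Representation,
    stim: StimulusSet,
    k: int | None = None,
    n_folds: int = 5,
    seed: int = 0,
) -> tuple[pd.Series, float]:
    """Cross-validated LDA sign-rule accuracy per class pair and overall.

    Per fold, PCA + LDA are fit on the training trials and each held-out
    trial is classified by the sign of its decision variable. Returns the
    per-pair accuracies (indexed by pair string) and their mean.
    """
    per_pair: dict[str, float] = {}
    for pair in stim.class_pairs():
        X, labels, _ = _pair_subset(rep, stim, pair, None)
        _check_folds(labels, pair, n_folds)
        y = labels == pair.class_b
        correct = 0
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        for train, test in skf.split(X, y):
            center, _, _, Vt, rank = _centered_svd(X[train])
            k_eff = default_k(train.size, rank) if k is None else min(int(k), rank)
            basis = _fix_signs(Vt[:k_eff].T.copy())
            Ztr = (X[train] - center) @ basis
            w, offset = fit_lda_axis(Ztr, y[train])
            if (Ztr[y[train]] @ w).mean() < (Ztr[~y[train]] @ w).mean():
                w, offset = -w, -offset
            dv_te = ((X[test] - center) @ basis) @ w - offset
            correct += int(((dv_te > 0) == y[test]).sum())
        per_pair[str(pair)] = correct / labels.size
    series = pd.Series(per_pair, name="accuracy").sort_index()
    return series, float(series.mean())
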