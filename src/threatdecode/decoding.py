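"""L2-regularized logistic decoding scored by forced-choice accuracy.

The classifier minimizes

    sum_i log(1 + exp(-y_i (w . x_i + b))) + ||w||^2 / (2 c)

with labels y in {-1, +1} (CS+ = +1), an unpenalized intercept, and
inverse-regularization c > 0 selected from 20 equally spaced values in
[0.01, 100] by nested cross-validation on training data only. Performance is
the forced-choice accuracy: for each held-out participant the decision
values of the CS+ and CS- maps are compared and the higher one is called
CS+, a criterion invariant to participant-level offsets and any strictly
increasing transform of the decision function.

Cross-validation splits participants (never maps) into 5 folds, repeats the
split 10 times with different seeds, and averages. The trainer solves the
objective with L-BFGS; when features outnumber training rows it first
reparameterizes exactly through a thin SVD of the training design (the
optimum lies in the row space because the orthogonal component is purely
penalized), and it can solve many label assignments of the same design in
one stacked call — the workhorse behind permutation tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .datasets import BetaMapSet, FeatureMatrix

DEFAULT_GRID: tuple[float, ...] = tuple(np.linspace(0.01, 100.0, 20))


@dataclass
class CVConfig:
    """Cross-validation settings (outer folds, repeats, inner selection)."""

    k: int = 5
    repeats: int = 10
    inner_k: int = 5
    grid: tuple[float, ...] = DEFAULT_GRID
    seed: int = 0
    tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("need at least 2 outer folds")
        if any(c <= 0 for c in self.grid):
            raise ValueError("inverse-regularization grid must be positive")


@dataclass
class DecoderModel:
    """Trained linear decoder: weights, intercept, and its feature contract."""

    w: np.ndarray
    b: float
    c: float
    feature_space_id: str = ""
    trained_on: str = ""

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if self.c <= 0:
            raise ValueError("inverse-regularization must be positive")

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[-1] != self.w.size:
            raise ValueError(
                f"feature dimension {X.shape[-1]} != model weights {self.w.size}"
            )
        return X @ self.w + self.b

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "w": self.w.tolist(),
                    "b": float(self.b),
                    "c": float(self.c),
                    "feature_space_id": self.feature_space_id,
                    "trained_on": self.trained_on,
                },
                fh,
            )

    @classmethod
    def load(cls, path) -> "DecoderModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(np.asarray(d["w"]), d["b"], d["c"], d["feature_space_id"], d["trained_on"])


@dataclass
class AccuracyResult:
    """Forced-choice accuracy with per-participant correctness."""

    accuracy: float
    per_participant: np.ndarray     # mean correctness per participant, in [0, 1]
    n: int
    contrast: str = ""
    block: str = ""

    def __post_init__(self) -> None:
        self.per_participant = np.asarray(self.per_participant, dtype=float)
        if not np.isclose(self.accuracy, self.per_participant.mean()):
            raise ValueError("accuracy must equal the mean per-participant correctness")


# --------------------------------------------------------------------------
# solver
# --------------------------------------------------------------------------

def _fit_batch(Z, Y, c, tol: float = 1e-6, maxiter: int = 20000):
    """Solve m independent logistic problems sharing the design ``Z``.

    Z: (n, q) design. Y: (n, m) labels in {-1, +1}. c: scalar or (m,)
    inverse-regularization per problem. Returns W (q, m), B (m,). The
    problems are stacked into one L-BFGS solve; the objective is separable,
    so the joint optimum is the per-problem optimum, with convergence
    declared when the gradient max-norm falls below ``tol``.
    """
    Z = np.asarray(Z, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, q = Z.shape
    m = Y.shape[1]
    c_inv = 1.0 / np.broadcast_to(np.asarray(c, dtype=float), (m,))

    def fg(theta):
        Th = theta.reshape(q + 1, m)
        W, B = Th[:q], Th[q]
        M = Y * (Z @ W + B)
        # stable single-exp evaluation of log(1 + exp(-M)) and sigma(-M)
        E = np.exp(-np.abs(M))
        loss = (np.log1p(E) + np.maximum(-M, 0.0)).sum()
        loss += 0.5 * float((c_inv * (W * W).sum(axis=0)).sum())
        S = -Y * np.where(M >= 0, E / (1.0 + E), 1.0 / (1.0 + E))
        G = np.empty((q + 1, m))
        G[:q] = Z.T @ S + W * c_inv
        G[q] = S.sum(axis=0)
        return loss, G.ravel()

    res = minimize(
        fg,
        np.zeros((q + 1) * m),
        jac=True,
        method="L-BFGS-B",
        options=dict(maxiter=maxiter, ftol=1e-16, gtol=tol),
    )
    Th = res.x.reshape(q + 1, m)
    return Th[:q], Th[q]


def _reduce_design(X):
    """Exact thin-SVD reparameterization when features outnumber rows."""
    if X.shape[1] <= X.shape[0]:
        return X, None
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    return U * S, Vt


def train_ridge_logistic(
    X: np.ndarray,
    y: np.ndarray,
    c: float,
    tol: float = 1e-6,
    feature_space_id: str = "",
    trained_on: str = "",
) -> DecoderModel:
    """Fit the L2-logistic objective; labels ``y`` in {-1, +1} (CS+ = +1)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("non-finite features")
    if not (np.any(y > 0) and np.any(y < 0)):
        raise ValueError("training data must contain both classes")
    if c <= 0:
        raise ValueError("inverse-regularization must be positive")
    Z, Vt = _reduce_design(X)
    W, B = _fit_batch(Z, y, c, tol=tol)
    w = W[:, 0] if Vt is None else Vt.T @ W[:, 0]
    return DecoderModel(w, float(B[0]), float(c), feature_space_id, trained_on)


# --------------------------------------------------------------------------
# forced choice
# --------------------------------------------------------------------------

def _pair_correctness(score_diff: np.ndarray) -> np.ndarray:
    """1 if CS+ scored higher, 0 if lower, 0.5 on an exact tie."""
    return np.where(score_diff > 0, 1.0, np.where(score_diff < 0, 0.0, 0.5))


def forced_choice_accuracy(
    model: DecoderModel, x_plus: np.ndarray, x_minus: np.ndarray, contrast: str = ""
) -> AccuracyResult:
    """Score participant-paired maps by the forced-choice rule."""
    diff = model.decision_values(x_plus) - model.decision_values(x_minus)
    per = _pair_correctness(diff)
    return AccuracyResult(float(per.mean()), per, int(per.size), contrast=contrast)


# --------------------------------------------------------------------------
# cross-validation core
# --------------------------------------------------------------------------

def _inner_best_c(Z, T, swaps, cv: CVConfig, rng: np.random.Generator) -> np.ndarray:
    """Select c per label assignment by inner-k-fold forced-choice accuracy.

    Z: reduced design of all 2T training rows ([CS+ rows; CS- rows]).
    swaps: (m, T) +-1 label assignment per training participant. Returns the
    chosen grid index per assignment; ties break toward the smaller c.
    """
    n_c = len(cv.grid)
    m = swaps.shape[0]
    order = rng.permutation(T)
    folds = np.array_split(order, cv.inner_k)
    acc = np.zeros((n_c, m))
    for fold in folds:
        tr = np.setdiff1d(order, fold)
        rows = np.concatenate([tr, tr + T])
        Ytr = np.concatenate([swaps[:, tr], -swaps[:, tr]], axis=1).T  # (2Ttr, m)
        Ytile = np.tile(Ytr, (1, n_c))
        c_vec = np.repeat(np.asarray(cv.grid, dtype=float), m)
        W, B = _fit_batch(Z[rows], Ytile, c_vec, tol=cv.tol)
        diff = (Z[fold] - Z[fold + T]) @ W  # (n_test, n_c*m); intercept cancels
        corr = _pair_correctness(diff * np.tile(swaps[:, fold].T, (1, n_c)))
        acc += corr.mean(axis=0).reshape(n_c, m)
    return np.argmax(acc, axis=0)


def _fold_fit(Z, T, swaps, cv: CVConfig, rng: np.random.Generator):
    """Train one outer fold's models for every label assignment.

    Returns W (q, m), B (m,). When the grid has a single value this is one
    stacked fit; otherwise the inner loop picks c per assignment first.
    """
    m = swaps.shape[0]
    Y = np.concatenate([swaps, -swaps], axis=1).T  # (2T, m)
    if len(cv.grid) == 1:
        return _fit_batch(Z, Y, cv.grid[0], tol=cv.tol)
    best = _inner_best_c(Z, T, swaps, cv, rng)
    q = Z.shape[1]
    W = np.empty((q, m))
    B = np.empty(m)
    for ci in np.unique(best):
        cols = np.flatnonzero(best == ci)
        Wc, Bc = _fit_batch(Z, Y[:, cols], cv.grid[ci], tol=cv.tol)
        W[:, cols], B[cols] = Wc, Bc
    return W, B


def _cv_forced_choice(Xp, Xm, swaps, cv: CVConfig):
    """Repeated k-fold forced-choice CV for many label assignments at once.

    Xp, Xm: (N, k) participant-paired feature maps. swaps: (m, N) +-1; row 0
    is typically the identity (observed labels) and further rows are
    within-participant label permutations. Returns (accuracy (m,),
    per_participant (m, N)) averaged over folds and repeats.
    """
    Xp = np.asarray(Xp, dtype=float)
    Xm = np.asarray(Xm, dtype=float)
    swaps = np.asarray(swaps, dtype=float)
    N = Xp.shape[0]
    if N < cv.k:
        raise ValueError(f"fewer participants ({N}) than folds ({cv.k})")
    correct = np.zeros((swaps.shape[0], N))
    for rep in range(cv.repeats):
        rng = np.random.default_rng(cv.seed + rep)
        order = rng.permutation(N)
        for fold in np.array_split(order, cv.k):
            train = np.setdiff1d(order, fold)
            T = train.size
            Xtr = np.concatenate([Xp[train], Xm[train]], axis=0)
            Z, Vt = _reduce_design(Xtr)
            W, B = _fold_fit(Z, T, swaps[:, train], cv, rng)
            dtest = Xp[fold] - Xm[fold]
            if Vt is not None:
                dtest = dtest @ Vt.T
            diff = dtest @ W  # (n_test, m); intercept cancels in the pair
            correct[:, fold] += _pair_correctness(diff.T * swaps[:, fold])
    per = correct / cv.repeats
    return per.mean(axis=1), per


def _resolve_features(data, selector=None) -> FeatureMatrix:
    if isinstance(data, FeatureMatrix):
        return data
    if isinstance(data, BetaMapSet):
        if selector is not None:
            from .masks import extract_features

            return extract_features(data, selector)
        n, c, v = data.values.shape
        return FeatureMatrix(
            data.values, list(data.participants), list(data.conditions),
            np.arange(v), data.grid_shape, data.site,
        )
    raise TypeError("expected a BetaMapSet or FeatureMatrix")


def crossvalidate_decoding(data, contrast, cv: CVConfig, selector=None) -> AccuracyResult:
    """Repeated participant-level 5-fold CV for one trial-block contrast."""
    features = _resolve_features(data, selector)
    Xp, Xm = features.pairs(contrast)
    acc, per = _cv_forced_choice(Xp, Xm, np.ones((1, Xp.shape[0])), cv)
    return AccuracyResult(
        float(acc[0]), per[0], Xp.shape[0],
        contrast=contrast.label, block=f"{contrast.phase}/TB{contrast.block}",
    )


def fit_decoder(data, contrast, cv: CVConfig, selector=None) -> DecoderModel:
    """Train one decoder on the full cohort (inner CV selects c)."""
    features = _resolve_features(data, selector)
    Xp, Xm = features.pairs(contrast)
    N = Xp.shape[0]
    X = np.concatenate([Xp, Xm], axis=0)
    y = np.concatenate([np.ones(N), -np.ones(N)])
    if len(cv.grid) == 1:
        c = cv.grid[0]
    else:
        Z, _ = _reduce_design(X)
        rng = np.random.default_rng(cv.seed)
        best = _inner_best_c(Z, N, np.ones((1, N)), cv, rng)
        c = cv.grid[int(best[0])]
    model = train_ridge_logistic(
        X, y, c, tol=cv.tol,
        feature_space_id=features.feature_space_id, trained_on=contrast.label,
    )
    return model


def apply_decoder(model: DecoderModel, data, contrast, selector=None) -> AccuracyResult:
    """Score an external dataset with frozen weights (no refitting).

    The external features must have been extracted through the same voxel
    index record as the training features (feature-space contract).
    """
    features = _resolve_features(data, selector)
    if model.feature_space_id and features.feature_space_id != model.feature_space_id:
        raise ValueError(
            "external features were not extracted through the decoder's voxel index record"
        )
    Xp, Xm = features.pairs(contrast)
    res = forced_choice_accuracy(model, Xp, Xm, contrast=contrast.label)
    res.block = f"{contrast.phase}/TB{contrast.block}"
    return res
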