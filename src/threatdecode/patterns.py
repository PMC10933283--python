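"""Haufe predictive patterns with bootstrap stabilization and a
label-permutation voxel null.

A linear decoder's weight vector w is a backward (extraction) filter and is
not directly interpretable voxel by voxel; the corresponding forward
(encoding) pattern is a = Cov(X) w, the Haufe transform. Its sign is
meaningful: a_v > 0 means voxel v is more activated by CS+ presentations.
Per-voxel significance comes from a within-participant label-swap null: the
pattern is re-estimated under many permutations, z = (a - mu0) / sigma0,
two-tailed normal p, Benjamini-Hochberg q.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .decoding import DecoderModel, _fit_batch, _reduce_design, _resolve_features
from .stats import fdr_bh


@dataclass
class PredictivePattern:
    """Per-voxel predictive weights with optional permutation inference."""

    a: np.ndarray
    z: np.ndarray | None = None
    p: np.ndarray | None = None
    q: np.ndarray | None = None
    degenerate: np.ndarray | None = None   # voxels with a zero-variance null
    contrast: str = ""

    def significant(self, alpha: float = 0.05) -> np.ndarray:
        if self.q is None:
            raise ValueError("no permutation inference attached")
        return self.q < alpha


def haufe_transform(model: DecoderModel, X: np.ndarray) -> np.ndarray:
    """Forward pattern a = Cov(X) w over the training rows (both classes).

    Computed as centered cross-products so the V x V covariance is never
    materialized; the scale is reported as-is (relative magnitudes carry the
    interpretation).
    """
    X = np.asarray(X, dtype=float)
    if X.shape[1] != model.w.size:
        raise ValueError("feature matrix does not match the model's weight length")
    Xc = X - X.mean(axis=0)
    return Xc.T @ (Xc @ model.w) / (X.shape[0] - 1)


def _pattern_for_labels(Xp, Xm, swaps, c, tol=1e-6) -> np.ndarray:
    """Haufe patterns for many label assignments of one paired cohort.

    swaps: (m, N) +-1 per participant. Returns (m, V). The covariance factor
    is label-free, so all assignments share the design and its reduction.
    """
    N = Xp.shape[0]
    X = np.concatenate([Xp, Xm], axis=0)
    Z, Vt = _reduce_design(X)
    Y = np.concatenate([swaps, -swaps], axis=1).T
    W, _ = _fit_batch(Z, Y, c, tol=tol)
    Zc = Z - Z.mean(axis=0)
    A = Zc.T @ (Zc @ W) / (2 * N - 1)       # patterns in reduced coordinates
    return A.T @ Vt if Vt is not None else A.T


def estimate_predictive_pattern(
    data, contrast, c: float, n_boot: int = 10, seed: int = 0, selector=None,
    tol: float = 1e-6,
) -> PredictivePattern:
    """Bootstrap-averaged Haufe pattern (participants resampled with
    replacement, model retrained each time). ``n_boot=0`` gives the plain
    full-sample pattern."""
    features = _resolve_features(data, selector)
    Xp, Xm = features.pairs(contrast)
    N = Xp.shape[0]
    if N < 2:
        raise ValueError("need at least 2 participants")
    rng = np.random.default_rng(seed)
    if n_boot == 0:
        a = _pattern_for_labels(Xp, Xm, np.ones((1, N)), c, tol)[0]
        return PredictivePattern(a, contrast=contrast.label)
    patterns = []
    for _ in range(n_boot):
        idx = rng.integers(0, N, size=N)
        patterns.append(_pattern_for_labels(Xp[idx], Xm[idx], np.ones((1, N)), c, tol)[0])
    return PredictivePattern(np.mean(patterns, axis=0), contrast=contrast.label)


def permutation_voxel_significance(
    data, contrast, c: float, n_perm: int = 1000, seed: int = 0, selector=None,
    tol: float = 1e-6, batch: int = 250,
) -> PredictivePattern:
    """Voxel-wise significance of the predictive pattern.

    Each permutation swaps the CS+/CS- maps independently per participant
    (respecting the paired structure) and re-estimates the Haufe pattern,
    giving a per-voxel null mean mu0 and SD sigma0; z = (a - mu0) / sigma0,
    p = 2 Phi(-|z|), q by Benjamini-Hochberg. Voxels with sigma0 = 0 are
    flagged degenerate and get p = 1.
    """
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    features = _resolve_features(data, selector)
    Xp, Xm = features.pairs(contrast)
    N, V = Xp.shape
    rng = np.random.default_rng(seed)
    observed = _pattern_for_labels(Xp, Xm, np.ones((1, N)), c, tol)[0]

    # streaming moments of the null, permutations solved in stacked batches
    s1 = np.zeros(V)
    s2 = np.zeros(V)
    done = 0
    while done < n_perm:
        m = min(batch, n_perm - done)
        swaps = rng.integers(0, 2, size=(m, N)) * 2.0 - 1.0
        null = _pattern_for_labels(Xp, Xm, swaps, c, tol)
        s1 += null.sum(axis=0)
        s2 += (null**2).sum(axis=0)
        done += m
    mu0 = s1 / n_perm
    var0 = np.maximum(s2 / n_perm - mu0**2, 0.0)
    sigma0 = np.sqrt(var0)

    degenerate = sigma0 == 0.0
    z = np.zeros(V)
    z[~degenerate] = (observed[~degenerate] - mu0[~degenerate]) / sigma0[~degenerate]
    p = 2.0 * norm.sf(np.abs(z))
    p[degenerate] = 1.0
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    q, _ = fdr_bh(p)
    return PredictivePattern(observed, z, p, q, degenerate, contrast.label)
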