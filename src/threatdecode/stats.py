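"""Inferential statistics for decoding results.

Accuracy significance uses a within-participant label-permutation test that
reruns the full cross-validation pipeline per permutation. External-cohort
accuracies are tested with the exact two-sided binomial test
(minimum-likelihood definition), group-level correct-decoding proportions
with a Pearson chi-square plus odds ratio and Wald 95% CI, and families of
tests are adjusted with Benjamini-Hochberg FDR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .decoding import CVConfig, _cv_forced_choice, _resolve_features


@dataclass
class PermutationTestResult:
    observed: float
    null_values: np.ndarray
    p: float
    n_perm: int
    contrast: str = ""

    def __post_init__(self) -> None:
        self.null_values = np.asarray(self.null_values, dtype=float)
        if not (0.0 < self.p <= 1.0):
            raise ValueError("permutation p must lie in (0, 1]")

    @property
    def report(self) -> str:
        bound = 1.0 / (self.n_perm + 1)
        return f"p < {bound:.3g}" if self.p <= bound else f"p = {self.p:.3g}"


@dataclass
class ProportionComparison:
    table: np.ndarray
    chi2: float
    df: int
    p: float
    or_: float
    ci95: tuple[float, float]
    continuity_corrected: bool = False
    zero_cell_adjusted: bool = False


def permutation_test_accuracy(
    data, contrast, cv: CVConfig, n_perm: int = 1000, seed: int = 0,
    selector=None, add_one: bool = True,
) -> PermutationTestResult:
    """One-sided permutation test for cross-validated forced-choice accuracy.

    Each permutation swaps the CS+/CS- maps within participants and reruns
    the identical CV pipeline; the observed accuracy is compared with the
    null accuracies. With ``add_one`` (default) p = (r + 1) / (n_perm + 1),
    which can never be zero; ``add_one=False`` counts the raw exceedance
    fraction, reported as a bound via :attr:`PermutationTestResult.report`
    when no null value reaches the observed accuracy.
    """
    if n_perm < 99:
        raise ValueError("need at least 99 permutations")
    features = _resolve_features(data, selector)
    Xp, Xm = features.pairs(contrast)
    N = Xp.shape[0]
    rng = np.random.default_rng(seed)
    swaps = np.ones((n_perm + 1, N))
    swaps[1:] = rng.integers(0, 2, size=(n_perm, N)) * 2.0 - 1.0
    accs, _ = _cv_forced_choice(Xp, Xm, swaps, cv)
    observed, null = float(accs[0]), accs[1:]
    r = int((null >= observed).sum())
    p = (r + 1) / (n_perm + 1) if add_one else max(r / n_perm, np.finfo(float).tiny)
    return PermutationTestResult(observed, null, float(p), n_perm, contrast.label)


def binomial_two_sided(k: int, n: int, p0: float = 0.5) -> float:
    """Exact two-sided binomial p (sum of outcomes no more likely than k)."""
    if not (0 <= k <= n) or n <= 0:
        raise ValueError("need 0 <= k <= n with n > 0")
    if not (0.0 < p0 < 1.0):
        raise ValueError("chance level must lie strictly between 0 and 1")
    return float(sps.binomtest(int(k), int(n), p0).pvalue)


def chisq_or_ci(a: int, b: int, c: int, d: int,
                continuity: bool = False) -> ProportionComparison:
    """Compare two correct/incorrect proportions from a 2x2 table
    [[a, b], [c, d]] (rows = groups, columns = correct/incorrect).

    Pearson chi-square (df = 1, no continuity correction by default), odds
    ratio ad/(bc), and Wald 95% CI on the log odds ratio. A zero cell
    triggers the Haldane-Anscombe +0.5 adjustment for the OR/CI (flagged).
    """
    table = np.array([[a, b], [c, d]], dtype=float)
    if np.any(table < 0):
        raise ValueError("counts must be nonnegative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("both margins must be positive")
    chi2, p, df, _ = sps.chi2_contingency(table, correction=continuity)
    zero = bool(np.any(table == 0))
    t = table + 0.5 if zero else table
    or_ = (t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0])
    se = np.sqrt((1.0 / t).sum())
    lo, hi = np.exp(np.log(or_) + np.array([-1.96, 1.96]) * se)
    return ProportionComparison(table.astype(int), float(chi2), int(df), float(p),
                                float(or_), (float(lo), float(hi)),
                                continuity_corrected=continuity, zero_cell_adjusted=zero)


def fdr_bh(pvals, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjustment.

    Returns (q, mask) where q_(i) = min_{j >= i} p_(j) m / j capped at 1 and
    mask = q < alpha.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, q < alpha
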