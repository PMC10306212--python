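"""Genomic inflation factor from QQ quantiles, and p-value corrections.

With only genes carrying case variants ever tested, the usual median-based
genomic control is unusable, so the inflation factor is estimated as the
through-origin slope of observed vs. expected -log10(p) restricted to QQ
points between the 0.5 and 0.95 expected quantiles — the window excludes the
inflated extremes of the plot.  Correction multiplies each raw p by the
inflation factor (only when it exceeds 1: deflating p-values would be
anti-conservative) and then by the number of tests (Bonferroni), capping at 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class QQData:
    """Paired expected and observed -log10(p), sorted by expected value."""

    expected: np.ndarray
    observed: np.ndarray

    def __post_init__(self) -> None:
        if len(self.expected) != len(self.observed):
            raise ValueError("expected and observed lengths differ")

    def to_frame(self, window: tuple[float, float] = (0.5, 0.95)) -> pd.DataFrame:
        n = len(self.expected)
        # expected values are -log10(i/(n+1)); recover the quantile rank
        rank_quantile = 10.0 ** (-self.expected)
        in_window = (rank_quantile >= window[0]) & (rank_quantile <= window[1])
        return pd.DataFrame(
            {
                "expected": self.expected,
                "observed": self.observed,
                "in_window": in_window,
            }
        )


@dataclass(frozen=True)
class LambdaEstimate:
    """Quantile-window inflation factor (through-origin QQ slope)."""

    lambda_: float
    window: tuple[float, float]
    n_points_used: int
    n_pvalues: int
    stable: bool = True

    def __post_init__(self) -> None:
        if self.lambda_ <= 0:
            raise ValueError("inflation factor must be positive")


def _check_pvalues(pvalues) -> np.ndarray:
    p = np.asarray(pvalues, dtype=float)
    if p.size < 1:
        raise ValueError("need at least one p-value")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    return p


def qq_points(pvalues) -> QQData:
    """Observed vs. expected -log10(p) under the uniform null.

    The i-th smallest p-value is paired with expected quantile i/(n+1); the
    output is sorted by expected value (ascending), i.e. largest p first.
    """
    p = np.sort(_check_pvalues(pvalues))
    n = p.size
    ranks = np.arange(1, n + 1)
    expected = -np.log10(ranks / (n + 1))
    observed = -np.log10(p)
    order = np.argsort(expected)
    return QQData(expected=expected[order], observed=observed[order])


def estimate_lambda(
    pvalues,
    window: tuple[float, float] = (0.5, 0.95),
    min_n: int = 20,
) -> LambdaEstimate:
    """Inflation factor lambda over the given expected-quantile window.

    QQ points whose expected quantile rank i/(n+1) lies within the window are
    kept and a least-squares line through the origin is fitted to (expected,
    observed) -log10(p); lambda is its slope.  With fewer than ``min_n``
    p-values the estimate is unstable and lambda falls back to 1 with a
    warning.
    """
    if not 0.0 <= window[0] < window[1] <= 1.0:
        raise ValueError("window bounds must satisfy 0 <= lower < upper <= 1")
    p = np.sort(_check_pvalues(pvalues))
    n = p.size
    if n < min_n:
        warnings.warn(
            f"only {n} p-values (< {min_n}); inflation estimate unstable, lambda = 1",
            stacklevel=2,
        )
        return LambdaEstimate(1.0, window, 0, n, stable=False)
    quantile = np.arange(1, n + 1) / (n + 1)
    sel = (quantile >= window[0]) & (quantile <= window[1])
    x = -np.log10(quantile[sel])
    y = -np.log10(p[sel])
    sxx = float((x * x).sum())
    if sxx == 0.0:
        raise ValueError("all selected expected values are zero; cannot fit slope")
    return LambdaEstimate(
        lambda_=float((x * y).sum() / sxx),
        window=window,
        n_points_used=int(sel.sum()),
        n_pvalues=n,
    )


def correct_p(p_raw: float, lambda_: float, n_tests: int) -> tuple[float, float]:
    """(inflation-corrected p, Bonferroni-final p).

    The inflation factor multiplies the p-value only when it exceeds 1
    (correction "when necessary"); Bonferroni multiplies by the number of
    tests; both products cap at 1.  Significance convention downstream:
    final p <= 0.05.
    """
    if not 0.0 < p_raw <= 1.0:
        raise ValueError("p_raw must lie in (0, 1]")
    if lambda_ <= 0:
        raise ValueError("lambda must be positive")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    p_lambda = min(1.0, p_raw * max(lambda_, 1.0))
    p_final = min(1.0, p_lambda * n_tests)
    return p_lambda, p_final


def apply_corrections(results, lambda_: float) -> None:
    """Fill p_lambda / p_final on a list of burden results, in place."""
    for result in results:
        result.p_lambda, result.p_final = correct_p(
            result.p_raw, lambda_, max(result.n_tests, 1)
        )
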