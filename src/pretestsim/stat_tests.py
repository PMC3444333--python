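"""The three component tests: pooled-variance t, Mann-Whitney U, Shapiro-Wilk.

All tests are two-sided. Rejection, wherever a decision is taken, is
``p < alpha`` (strict); with continuous data the boundary has probability
zero, so the convention is immaterial but fixed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from . import _mwu, _shapiro
from .distributions import SamplePair
from .exceptions import DegenerateSampleError

__all__ = ["TestResult", "t_test_pooled", "mann_whitney_u", "shapiro_wilk"]


@dataclass(frozen=True)
class TestResult:
    """Outcome of a component test.

    ``statistic`` is T for the t test, U for the rank test, W for
    Shapiro-Wilk; ``df_or_n`` holds the t degrees of freedom or the
    sample size for the other two.
    """

    test_name: str  # "t" | "U" | "shapiro_wilk"
    statistic: float
    p_value: float
    df_or_n: float

    def to_record(self) -> dict:
        return {
            "test": self.test_name,
            "statistic": self.statistic,
            "p": self.p_value,
            "n_or_df": self.df_or_n,
        }


def t_test_pooled(pair: SamplePair) -> TestResult:
    """Student's two-sample t test assuming equal variances.

    T = (m_X - m_Y) / (s * sqrt(1/n_X + 1/n_Y)), with s the pooled
    standard deviation; two-sided p from the t distribution with
    n_X + n_Y - 2 degrees of freedom.
    """
    x, y = pair.x, pair.y
    nx, ny = len(x), len(y)
    df = nx + ny - 2
    ssq = ((x - x.mean()) ** 2).sum() + ((y - y.mean()) ** 2).sum()
    if ssq == 0.0:
        raise DegenerateSampleError("zero pooled variance: T is undefined")
    s = np.sqrt(ssq / df)
    t = (x.mean() - y.mean()) / (s * np.sqrt(1.0 / nx + 1.0 / ny))
    p = 2.0 * stats.t.sf(abs(t), df)
    return TestResult("t", float(t), float(p), float(df))


def mann_whitney_u(pair: SamplePair, mode: str = "auto") -> TestResult:
    """Mann-Whitney U test (two-sided).

    U counts pairs with x_i > y_j (ties 1/2). ``mode="auto"`` uses the
    exact permutation distribution for tie-free data with fewer than 50
    observations in total, otherwise the tie-corrected normal
    approximation with continuity correction; see :mod:`pretestsim._mwu`.
    """
    u, p = _mwu.batch_u_p(pair.x[None, :], pair.y[None, :], mode=mode)
    return TestResult("U", float(u[0]), float(p[0]), float(pair.n))


def shapiro_wilk(sample: np.ndarray) -> TestResult:
    """Shapiro-Wilk normality test (Royston AS R94 approximation)."""
    sample = np.asarray(sample, dtype=float)
    if sample.ndim != 1:
        raise ValueError("expected a one-dimensional sample")
    w, p = _shapiro.shapiro_w_p(sample[None, :])
    return TestResult("shapiro_wilk", float(w[0]), float(p[0]), float(sample.size))


# ---------------------------------------------------------------------
# batch kernels used by the Monte-Carlo engine (same math, vectorized)

def t_pvalues(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Two-sided pooled-t p-values for row-wise sample pairs."""
    x = np.atleast_2d(x)
    y = np.atleast_2d(y)
    nx, ny = x.shape[1], y.shape[1]
    df = nx + ny - 2
    ssq = ((x - x.mean(1, keepdims=True)) ** 2).sum(1)
    ssq += ((y - y.mean(1, keepdims=True)) ** 2).sum(1)
    s = np.sqrt(ssq / df)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (x.mean(1) - y.mean(1)) / (s * np.sqrt(1.0 / nx + 1.0 / ny))
    if np.any(~np.isfinite(t)):
        raise DegenerateSampleError("zero pooled variance in batch")
    return 2.0 * stats.t.sf(np.abs(t), df)


def u_pvalues(x: np.ndarray, y: np.ndarray, mode: str = "auto") -> np.ndarray:
    """Two-sided Mann-Whitney p-values for row-wise sample pairs."""
    return _mwu.batch_u_p(x, y, mode=mode)[1]


def shapiro_pvalues(samples: np.ndarray) -> np.ndarray:
    """Shapiro-Wilk p-values along the last axis."""
    return _shapiro.shapiro_w_p(samples)[1]
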