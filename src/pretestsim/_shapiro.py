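"""Vectorized Shapiro-Wilk W test (Royston's AS R94 approximation).

The W statistic is the squared correlation between the sample order
statistics and the expected normal order statistics; the p-value comes
from Royston's normalizing transformations of ``log(1 - W)`` (exact for
n = 3). The kernel evaluates whole batches of equal-length samples at
once, which is what makes rejection sampling on rare pretest outcomes
(acceptance rates down to ~1e-5) tractable.

Supported sizes: 3 <= n <= 5000, matching the range over which the
approximation is validated.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.special import ndtr, ndtri

from .exceptions import DegenerateSampleError, UnsupportedSampleSizeError

_MIN_N, _MAX_N = 3, 5000


@lru_cache(maxsize=None)
def _coefficients(n: int) -> np.ndarray:
    """Royston's weights a_1..a_n (antisymmetric, unit norm)."""
    m = ndtri((np.arange(1, n + 1) - 0.375) / (n + 0.25))
    mm = float(m @ m)
    c = m / np.sqrt(mm)
    a = np.empty(n)
    if n == 3:
        r = np.sqrt(0.5)
        return np.array([-r, 0.0, r])
    u = 1.0 / np.sqrt(n)
    # polynomial corrections to the last (and second-to-last) weight
    a_n = (c[-1] + 0.221157 * u - 0.147981 * u**2 - 2.071190 * u**3
           + 4.434685 * u**4 - 2.706056 * u**5)
    if n <= 5:
        phi = (mm - 2 * m[-1] ** 2) / (1 - 2 * a_n**2)
        a[1:-1] = m[1:-1] / np.sqrt(phi)
        a[0], a[-1] = -a_n, a_n
    else:
        a_n1 = (c[-2] + 0.042981 * u - 0.293762 * u**2 - 1.752461 * u**3
                + 5.682633 * u**4 - 3.582633 * u**5)
        phi = (mm - 2 * m[-1] ** 2 - 2 * m[-2] ** 2) / (1 - 2 * a_n**2 - 2 * a_n1**2)
        a[2:-2] = m[2:-2] / np.sqrt(phi)
        a[0], a[-1] = -a_n, a_n
        a[1], a[-2] = -a_n1, a_n1
    return a


def shapiro_w_p(samples: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """W statistics and p-values for a batch of samples.

    Parameters
    ----------
    samples : array, shape (..., n)
        Equal-length samples along the last axis.

    Returns
    -------
    W, p : arrays of shape ``samples.shape[:-1]``
    """
    x = np.asarray(samples, dtype=float)
    n = x.shape[-1]
    if not _MIN_N <= n <= _MAX_N:
        raise UnsupportedSampleSizeError(
            f"Shapiro-Wilk supports 3 <= n <= 5000, got n={n}"
        )
    a = _coefficients(n)
    xs = np.sort(x, axis=-1)
    ss = ((xs - xs.mean(axis=-1, keepdims=True)) ** 2).sum(axis=-1)
    if np.any(ss == 0.0):
        raise DegenerateSampleError("constant sample: W is undefined")
    w = np.minimum((xs @ a) ** 2 / ss, 1.0)

    if n == 3:
        p = 6.0 / np.pi * (
            np.arcsin(np.sqrt(np.clip(w, 0.75, 1.0))) - np.arcsin(np.sqrt(0.75))
        )
        return w, np.clip(p, 0.0, 1.0)

    log1mw = np.log1p(-np.minimum(w, 1.0 - 1e-15))
    if n <= 11:
        g = -2.273 + 0.459 * n
        mu = 0.5440 - 0.39978 * n + 0.025054 * n**2 - 0.0006714 * n**3
        sigma = np.exp(1.3822 - 0.77857 * n + 0.062767 * n**2 - 0.0020322 * n**3)
        z = (-np.log(g - log1mw) - mu) / sigma
    else:
        ln = np.log(n)
        mu = -1.5861 - 0.31082 * ln - 0.083751 * ln**2 + 0.0038915 * ln**3
        sigma = np.exp(-0.4803 - 0.082676 * ln + 0.0030302 * ln**2)
        z = (log1mw - mu) / sigma
    return w, 1.0 - ndtr(z)
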