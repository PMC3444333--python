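"""Sampling models for the simulation study.

Three population families are supported — exponential (parameterized by
rate), uniform on ``[a, b)``, and normal — the shapes used to emulate
skewed, short-tailed, and well-behaved clinical measurements. Null
configurations draw both groups from one spec; shifted alternatives pair
two different specs (e.g. rates 1.0 vs 2.0, or normal means 0.0 vs 0.6
at unit variance).

Reproducibility contract: every scenario derives its own independent
random substream from ``(root seed, scenario key)``, so results do not
depend on the order in which scenarios run.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigurationError

FAMILIES = ("exponential", "uniform", "normal")


@dataclass(frozen=True)
class DistributionSpec:
    """A named sampling model with family-specific parameters.

    Parameters
    ----------
    family : {"exponential", "uniform", "normal"}
    params : tuple of float
        ``(rate,)`` for exponential (rate > 0); ``(a, b)`` for uniform
        (a < b); ``(mean, sd)`` for normal (sd > 0).
    """

    family: str
    params: tuple[float, ...]

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ConfigurationError(
                f"unknown family {self.family!r}; expected one of {FAMILIES}"
            )
        object.__setattr__(self, "params", tuple(float(p) for p in self.params))
        p = self.params
        if self.family == "exponential":
            if len(p) != 1 or p[0] <= 0:
                raise ConfigurationError("exponential requires a single rate > 0")
        elif self.family == "uniform":
            if len(p) != 2 or not p[0] < p[1]:
                raise ConfigurationError("uniform requires bounds a < b")
        else:
            if len(p) != 2 or p[1] <= 0:
                raise ConfigurationError("normal requires (mean, sd) with sd > 0")

    # -- convenience constructors -------------------------------------
    @classmethod
    def exponential(cls, rate: float = 1.0) -> "DistributionSpec":
        return cls("exponential", (rate,))

    @classmethod
    def uniform(cls, a: float = 0.0, b: float = 1.0) -> "DistributionSpec":
        return cls("uniform", (a, b))

    @classmethod
    def normal(cls, mean: float = 0.0, sd: float = 1.0) -> "DistributionSpec":
        return cls("normal", (mean, sd))

    @property
    def mean(self) -> float:
        """Population mean implied by the parameters."""
        if self.family == "exponential":
            return 1.0 / self.params[0]
        if self.family == "uniform":
            return 0.5 * (self.params[0] + self.params[1])
        return self.params[0]

    @property
    def variance(self) -> float:
        if self.family == "exponential":
            return 1.0 / self.params[0] ** 2
        if self.family == "uniform":
            return (self.params[1] - self.params[0]) ** 2 / 12.0
        return self.params[1] ** 2

    def sample(self, size, rng: np.random.Generator) -> np.ndarray:
        """Draw i.i.d. values of the given shape from this model."""
        if self.family == "exponential":
            return rng.exponential(scale=1.0 / self.params[0], size=size)
        if self.family == "uniform":
            return rng.uniform(self.params[0], self.params[1], size=size)
        return rng.normal(self.params[0], self.params[1], size=size)

    def key(self) -> str:
        """Canonical string used in substream derivation."""
        return f"{self.family}({','.join(repr(p) for p in self.params)})"


@dataclass(frozen=True)
class SamplePair:
    """Two equal-length numeric samples (groups X and Y)."""

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if x.ndim != 1 or y.ndim != 1:
            raise ConfigurationError("samples must be one-dimensional")
        if len(x) != len(y):
            raise ConfigurationError("groups must have equal size")
        if len(x) < 3:
            raise ConfigurationError("per-group size must be >= 3")
        if not (np.isfinite(x).all() and np.isfinite(y).all()):
            raise ConfigurationError("samples must be finite")

    @property
    def n(self) -> int:
        return len(self.x)


def draw_sample(spec: DistributionSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Length-``n`` i.i.d. draw from ``spec``, advancing ``rng``."""
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    return spec.sample(int(n), rng)

def draw_pair(
    spec_x: DistributionSpec,
    spec_y: DistributionSpec,
    n: int,
    rng: np.random.Generator,
) -> SamplePair:
    """Independent group draws; under the null both specs are identical."""
    return SamplePair(draw_sample(spec_x, n, rng), draw_sample(spec_y, n, rng))


def substream(seed: int, *key_parts) -> np.random.Generator:
    """Independent, order-free random substream for one scenario.

    The scenario key is hashed (SHA-256) into extra entropy words mixed
    with the root seed, so each (seed, key) pair yields a reproducible
    stream that is statistically independent of every other scenario's.
    """
    digest = hashlib.sha256("/".join(str(p) for p in key_parts).encode()).digest()
    words = [int.from_bytes(digest[i : i + 4], "little") for i in range(0, 16, 4)]
    return np.random.default_rng(np.random.SeedSequence([int(seed), *words]))
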