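"""The two-stage decision procedure.

A preliminary Shapiro-Wilk test at level ``alpha_pre`` selects the main
analysis: if the pretest is *not* significant the pooled-variance t test
is run, otherwise Mann-Whitney's U test. Two gating strategies:

* Strategy I — the pretest is applied separately to each raw sample;
  both must pass for the t branch.
* Strategy II — one pretest on the collapsed set of within-group
  mean-centered residuals from both samples (the linear-model view of
  the normality assumption).

"Passing" means pretest p >= alpha_pre; the main test rejects iff its
p-value is strictly below ``alpha``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import stat_tests
from .distributions import SamplePair
from .exceptions import ConfigurationError
from .stat_tests import TestResult

__all__ = [
    "StrategyConfig",
    "TwoStageOutcome",
    "residuals",
    "pretest_pass",
    "two_stage_test",
]


@dataclass(frozen=True)
class StrategyConfig:
    """Pretest strategy and significance levels.

    ``alpha_pre=None`` means no pretest: the caller must force a branch
    (pure-t or pure-U runs, the "without pretest" table rows).
    """

    strategy: str = "I"  # "I" | "II"
    alpha_pre: float | None = 0.05
    alpha: float = 0.05

    def __post_init__(self):
        if self.strategy not in ("I", "II"):
            raise ConfigurationError("strategy must be 'I' or 'II'")
        if self.alpha_pre is not None and not 0.0 < self.alpha_pre < 1.0:
            raise ConfigurationError("alpha_pre must lie in (0, 1)")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigurationError("alpha must lie in (0, 1)")

    def key(self) -> str:
        return f"S{self.strategy},pre={self.alpha_pre},a={self.alpha}"


@dataclass(frozen=True)
class TwoStageOutcome:
    """Full record of one run of the procedure on one sample pair."""

    pretest_p: tuple[float, ...]  # two p-values (Strategy I) or one (II)
    pretest_passed: bool
    branch: str  # "t" | "U"
    main_result: TestResult
    reject: bool

    def to_record(self) -> dict:
        return {
            "pretest_p": list(self.pretest_p),
            "pretest_passed": self.pretest_passed,
            "branch": self.branch,
            "main": self.main_result.to_record(),
            "reject": self.reject,
        }


def residuals(pair: SamplePair) -> np.ndarray:
    """Collapsed within-group residuals: (x_i - m_X) then (y_i - m_Y)."""
    return np.concatenate([pair.x - pair.x.mean(), pair.y - pair.y.mean()])


def pretest_pass(pair: SamplePair, cfg: StrategyConfig) -> tuple[bool, tuple[float, ...]]:
    """Apply the configured pretest; returns (passed, pretest p-values)."""
    if cfg.alpha_pre is None:
        raise ConfigurationError("pretest_pass requires alpha_pre to be set")
    if cfg.strategy == "I":
        px = stat_tests.shapiro_wilk(pair.x).p_value
        py = stat_tests.shapiro_wilk(pair.y).p_value
        return (px >= cfg.alpha_pre and py >= cfg.alpha_pre), (px, py)
    pr = stat_tests.shapiro_wilk(residuals(pair)).p_value
    return pr >= cfg.alpha_pre, (pr,)


def two_stage_test(
    pair: SamplePair,
    cfg: StrategyConfig,
    force_branch: str | None = None,
) -> TwoStageOutcome:
    """Run the full procedure on one pair.

    With ``cfg.alpha_pre=None`` the branch must be forced ("t" or "U");
    otherwise the pretest decides and exactly one main test runs.
    """
    if cfg.alpha_pre is None:
        if force_branch not in ("t", "U"):
            raise ConfigurationError(
                "without a pretest, force_branch must be 't' or 'U'"
            )
        passed = force_branch == "t"
        pretest_p: tuple[float, ...] = ()
        branch = force_branch
    else:
        if force_branch is not None:
            raise ConfigurationError("force_branch conflicts with a configured pretest")
        passed, pretest_p = pretest_pass(pair, cfg)
        branch = "t" if passed else "U"
    main = (
        stat_tests.t_test_pooled(pair)
        if branch == "t"
        else stat_tests.mann_whitney_u(pair)
    )
    return TwoStageOutcome(pretest_p, passed, branch, main, main.p_value < cfg.alpha)
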