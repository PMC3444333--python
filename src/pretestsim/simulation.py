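"""Monte-Carlo estimators for conditional and unconditional error rates.

Three estimators, all pure functions of a :class:`ScenarioConfig`:

* :func:`conditional_rate` — rejection sampling: generate sample pairs,
  keep only those whose pretest outcome matches the conditioning event
  ("pass" -> t branch, "fail" -> U branch), until ``reps`` pairs are
  kept; the rate is the branch test's rejection fraction among them.
  If ``max_attempts`` is exhausted first, the condition is declared
  infeasible (the "N/A" cells of conditional-error tables).
* :func:`unconditional_rate` — every generated pair is analyzed by the
  full two-stage procedure (or a forced single branch).
* :func:`power_rate` — the same machinery under a shifted alternative.

Everything is evaluated in vectorized batches; a scenario's random
substream is derived from (seed, scenario key), so scenarios are
order-independent and individually reproducible. The generated stream
is laid out batch by batch, so ``batch_size`` is part of the stream
definition (default 20,000).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .distributions import DistributionSpec, substream
from .exceptions import ConfigurationError, InfeasibleConditionError
from .stat_tests import shapiro_pvalues, t_pvalues, u_pvalues
from .two_stage import StrategyConfig

logger = logging.getLogger(__name__)

__all__ = [
    "ScenarioConfig",
    "RateEstimate",
    "conditional_rate",
    "unconditional_rate",
    "power_rate",
    "run_scenario",
]

DEFAULT_BATCH = 20_000
#: default cap on generated pairs, as a multiple of ``reps``
MAX_ATTEMPTS_FACTOR = 1_000


@dataclass(frozen=True)
class ScenarioConfig:
    """One simulation scenario (a single table cell)."""

    spec_x: DistributionSpec
    spec_y: DistributionSpec
    n: int
    strategy_cfg: StrategyConfig
    null_or_alt: str = "null"  # "null" | "alternative"
    condition_on: str = "none"  # "pass" | "fail" | "none"
    force_branch: str | None = None  # "t" | "U" when no pretest
    reps: int = 10_000
    seed: int = 0
    max_attempts: int | None = None  # default MAX_ATTEMPTS_FACTOR * reps
    batch_size: int = DEFAULT_BATCH
    mwu_mode: str = "auto"

    def __post_init__(self):
        if self.null_or_alt not in ("null", "alternative"):
            raise ConfigurationError("null_or_alt must be 'null' or 'alternative'")
        if self.null_or_alt == "null" and self.spec_x != self.spec_y:
            raise ConfigurationError("null scenarios require spec_x == spec_y")
        if self.condition_on not in ("pass", "fail", "none"):
            raise ConfigurationError("condition_on must be 'pass', 'fail' or 'none'")
        if self.condition_on != "none" and self.strategy_cfg.alpha_pre is None:
            raise ConfigurationError("conditioning requires a pretest (alpha_pre)")
        if self.force_branch is not None and self.strategy_cfg.alpha_pre is not None:
            raise ConfigurationError("force_branch requires alpha_pre=None")
        if self.reps < 1:
            raise ConfigurationError("reps must be >= 1")
        if self.max_attempts is not None and self.max_attempts < self.reps:
            raise ConfigurationError("max_attempts must be >= reps")
        if self.n < 3:
            raise ConfigurationError("per-group n must be >= 3")

    @property
    def attempts_cap(self) -> int:
        return (
            self.max_attempts
            if self.max_attempts is not None
            else MAX_ATTEMPTS_FACTOR * self.reps
        )

    def key(self) -> tuple:
        """Scenario identity for substream derivation (reps excluded, so
        enlarging a run extends the same stream)."""
        return (
            "scenario",
            self.spec_x.key(),
            self.spec_y.key(),
            self.n,
            self.strategy_cfg.key(),
            self.condition_on,
            self.force_branch,
        )

    def rng(self) -> np.random.Generator:
        return substream(self.seed, *self.key())


@dataclass(frozen=True)
class RateEstimate:
    """Estimated rejection proportion with Monte-Carlo precision."""

    rate: float
    reps: int
    mc_se: float
    attempts: int
    acceptance_rate: float | None = None  # conditional runs only

    def to_record(self) -> dict:
        return {
            "rate": self.rate,
            "reps": self.reps,
            "mc_se": self.mc_se,
            "attempts": self.attempts,
            "acceptance_rate": self.acceptance_rate,
        }


def _estimate(n_reject: int, reps: int, attempts: int, acceptance) -> RateEstimate:
    rate = n_reject / reps
    return RateEstimate(rate, reps, float(np.sqrt(rate * (1 - rate) / reps)),
                        attempts, acceptance)


def _pretest_pass_mask(x: np.ndarray, y: np.ndarray, cfg: StrategyConfig) -> np.ndarray:
    """Vectorized pretest over row-wise pairs; True = passed (t branch)."""
    if cfg.strategy == "I":
        return (shapiro_pvalues(x) >= cfg.alpha_pre) & (
            shapiro_pvalues(y) >= cfg.alpha_pre
        )
    resid = np.concatenate(
        [x - x.mean(1, keepdims=True), y - y.mean(1, keepdims=True)], axis=1
    )
    return shapiro_pvalues(resid) >= cfg.alpha_pre


def conditional_rate(cfg: ScenarioConfig) -> RateEstimate:
    """Type I error (or power) of one branch, conditional on its pretest
    outcome, by rejection sampling."""
    if cfg.condition_on not in ("pass", "fail"):
        raise ConfigurationError("conditional_rate needs condition_on in {pass, fail}")
    rng = cfg.rng()
    scfg = cfg.strategy_cfg
    kept_x, kept_y = [], []
    kept = 0
    attempts = 0
    cap = cfg.attempts_cap
    while kept < cfg.reps:
        if attempts >= cap:
            err = InfeasibleConditionError(
                f"pretest condition '{cfg.condition_on}' matched only {kept} of "
                f"{attempts} generated pairs (acceptance ~{kept / attempts:.2e}); "
                f"max_attempts={cap} exhausted before reps={cfg.reps}",
                attempts=attempts,
                kept=kept,
            )
            logger.warning("infeasible condition: %s", err)
            raise err
        b = min(cfg.batch_size, cap - attempts)
        x = cfg.spec_x.sample((b, cfg.n), rng)
        y = cfg.spec_y.sample((b, cfg.n), rng)
        mask = _pretest_pass_mask(x, y, scfg)
        if cfg.condition_on == "fail":
            mask = ~mask
        idx = np.flatnonzero(mask)
        if kept + idx.size >= cfg.reps:
            last = idx[cfg.reps - kept - 1]
            idx = idx[: cfg.reps - kept]
            attempts += int(last) + 1
        else:
            attempts += b
        if idx.size:
            kept_x.append(x[idx])
            kept_y.append(y[idx])
            kept += idx.size
    x = np.concatenate(kept_x)
    y = np.concatenate(kept_y)
    if cfg.condition_on == "pass":
        p = t_pvalues(x, y)
    else:
        p = u_pvalues(x, y, mode=cfg.mwu_mode)
    acceptance = cfg.reps / attempts
    logger.info(
        "conditional run %s: acceptance %.4g (%d attempts for %d kept)",
        cfg.key(), acceptance, attempts, cfg.reps,
    )
    return _estimate(int((p < scfg.alpha).sum()), cfg.reps, attempts, acceptance)


def unconditional_rate(cfg: ScenarioConfig) -> RateEstimate:
    """Rejection rate of the entire two-stage procedure (or of a forced
    single branch) over all generated pairs."""
    if cfg.condition_on != "none":
        raise ConfigurationError("unconditional_rate needs condition_on='none'")
    scfg = cfg.strategy_cfg
    if scfg.alpha_pre is None and cfg.force_branch not in ("t", "U"):
        raise ConfigurationError("without a pretest, force_branch must be 't' or 'U'")
    rng = cfg.rng()
    n_reject = 0
    done = 0
    while done < cfg.reps:
        b = min(cfg.batch_size, cfg.reps - done)
        x = cfg.spec_x.sample((b, cfg.n), rng)
        y = cfg.spec_y.sample((b, cfg.n), rng)
        if scfg.alpha_pre is None:
            p = t_pvalues(x, y) if cfg.force_branch == "t" else u_pvalues(
                x, y, mode=cfg.mwu_mode
            )
            n_reject += int((p < scfg.alpha).sum())
        else:
            mask = _pretest_pass_mask(x, y, scfg)
            if mask.any():
                pt = t_pvalues(x[mask], y[mask])
                n_reject += int((pt < scfg.alpha).sum())
            if (~mask).any():
                pu = u_pvalues(x[~mask], y[~mask], mode=cfg.mwu_mode)
                n_reject += int((pu < scfg.alpha).sum())
        done += b
    return _estimate(n_reject, cfg.reps, cfg.reps, None)


def power_rate(cfg: ScenarioConfig) -> RateEstimate:
    """Power of the procedure under a shifted alternative (same machinery
    as :func:`unconditional_rate`; with identical specs it returns the
    size)."""
    if cfg.null_or_alt != "alternative":
        cfg = replace(cfg, null_or_alt="alternative")
    return unconditional_rate(cfg)


def run_scenario(cfg: ScenarioConfig) -> RateEstimate:
    """Dispatch on the conditioning mode."""
    if cfg.condition_on == "none":
        return unconditional_rate(cfg)
    return conditional_rate(cfg)
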