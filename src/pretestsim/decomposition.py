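"""Total-probability decomposition of the two-stage rejection rate.

The unconditional rejection probability of the procedure is the weighted
sum of the two branches' conditional rates,

    P(reject) = P(reject | pretest n.s.) * P(pretest n.s.)
              + P(reject | pretest sig.) * P(pretest sig.),

where the weights are the pretest's probabilities of (not) flagging
non-normality. Under exact normality the failure weight has a closed
form: 1 - (1 - alpha_pre)^2 for Strategy I (two independent pretests)
and approximately alpha_pre for Strategy II (a single pretest on the
collapsed residuals; approximate because the two residual halves are
not completely independent).
"""

from __future__ import annotations

from dataclasses import dataclass

from .exceptions import ConfigurationError

__all__ = ["DecompositionInput", "total_probability", "pretest_fail_weight"]


@dataclass(frozen=True)
class DecompositionInput:
    """Branch rates and pretest-failure weight, all probabilities."""

    p_reject_given_pass: float
    p_reject_given_fail: float
    p_pretest_fail: float

    def __post_init__(self):
        for name in ("p_reject_given_pass", "p_reject_given_fail", "p_pretest_fail"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")


def total_probability(d: DecompositionInput) -> float:
    """Unconditional rejection rate implied by the branch rates."""
    w = d.p_pretest_fail
    return d.p_reject_given_pass * (1.0 - w) + d.p_reject_given_fail * w


def pretest_fail_weight(strategy: str, alpha_pre: float) -> float:
    """Pretest failure probability under exact normality.

    Strategy I: 1 - (1 - alpha_pre)^2 (both samples must pass).
    Strategy II: alpha_pre (single pretest at its nominal size; only
    approximate, since the residual halves are weakly dependent).
    """
    if not 0.0 < alpha_pre < 1.0:
        raise ConfigurationError("alpha_pre must lie in (0, 1)")
    if strategy == "I":
        return 1.0 - (1.0 - alpha_pre) ** 2
    if strategy == "II":
        return alpha_pre
    raise ConfigurationError("strategy must be 'I' or 'II'")
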