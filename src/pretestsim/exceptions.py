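"""Typed errors raised by the simulation and testing machinery."""


class ConfigurationError(ValueError):
    """Invalid distribution family, parameters, or scenario settings."""


class DegenerateSampleError(ValueError):
    """A sample is constant (zero variance), so the requested test statistic
    is undefined."""


class UnsupportedSampleSizeError(ValueError):
    """Sample size outside the supported range of a test (Shapiro-Wilk
    requires 3 <= n <= 5000)."""


class InfeasibleConditionError(RuntimeError):
    """Rejection sampling exhausted ``max_attempts`` before collecting the
    requested number of conditioned replicates.

    This is the mechanism behind 'N/A' cells in conditional-error tables:
    when the pretest outcome being conditioned on has practically zero
    probability, the target replicate count cannot be reached.
    """

    def __init__(self, message: str, *, attempts: int, kept: int):
        super().__init__(message)
        self.attempts = attempts
        self.kept = kept

    @property
    def acceptance_rate(self) -> float:
        """Observed fraction of generated pairs matching the condition."""
        return self.kept / self.attempts if self.attempts else 0.0
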