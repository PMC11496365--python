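"""Exception hierarchy for triageq."""


class TriageQError(Exception):
    """Base class for all triageq errors."""


class ConfigError(TriageQError):
    """Invalid or inconsistent workflow configuration."""


class InstabilityError(TriageQError):
    """The queueing system is unstable (utilization at or above capacity)."""


class InfeasibleMomentsError(TriageQError):
    """Moment triple cannot belong to a nonnegative distribution, or no
    phase-type fit could be found for it."""


class SolverError(TriageQError):
    """Matrix-geometric solver failed to converge or produced an invalid
    stationary distribution."""


class UnsupportedConfigurationError(TriageQError):
    """Configuration outside the analytic coverage of the workflow models
    (e.g. distinct diseased/non-diseased read times with more than one
    radiologist)."""
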