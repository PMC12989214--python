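"""Exception hierarchy.

Analysis-outcome failures (an exposure that cannot be instrumented) are kept
distinct from configuration and I/O errors so that a screening run can isolate
per-exposure failures without masking genuine bugs.
"""


class MRMediateError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MRMediateError):
    """Bad configuration: missing column, unknown group label, missing SNP in LD."""


class ValidationError(MRMediateError):
    """A record violates a type invariant (se <= 0, eaf outside [0, 1], ...)."""


class HarmonizationError(MRMediateError):
    """Exposure and outcome tables cannot be harmonized."""


class NoSharedInstrumentsError(HarmonizationError):
    """Exposure and outcome share no SNPs (distinct from an empty input)."""


class InsufficientInstrumentsError(MRMediateError):
    """An estimator received fewer instruments than it requires."""


class DegenerateInstrumentError(MRMediateError):
    """A Wald ratio was requested for an instrument with zero exposure effect."""


class NotInstrumentableError(MRMediateError):
    """An exposure failed an instrument-selection gate.

    Parameters
    ----------
    gate:
        Short machine-readable name of the failing gate, e.g. ``"min_snps"``
        or ``"min_total_r2"``.
    """

    def __init__(self, gate: str, message: str | None = None):
        self.gate = gate
        super().__init__(message or f"exposure not instrumentable: {gate}")


class SimulationError(MRMediateError):
    """Infeasible simulation parameterization (e.g. unreachable case fraction)."""
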