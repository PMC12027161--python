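"""Exception hierarchy shared across the pipeline stages."""


class LoadRiskError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(LoadRiskError, ValueError):
    """A parameter is outside its documented domain."""


class AlignmentError(LoadRiskError, ValueError):
    """Two tables that must share an id set or SNP set do not."""


class DegenerateDataError(LoadRiskError, ValueError):
    """Input is structurally valid but statistically degenerate
    (zero variance controls, single-class labels, zero-norm vector...)."""


class StratificationError(LoadRiskError, ValueError):
    """A cross-validation fold or split cannot contain both classes."""


class SimulationExhaustedError(LoadRiskError, RuntimeError):
    """The cohort generator could not reach the requested class counts."""


class NoThresholdError(LoadRiskError, ValueError):
    """No threshold in the sweep satisfies the requested constraint."""
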