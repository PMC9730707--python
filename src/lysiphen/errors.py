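"""Exception types shared across the package."""


class LysiphenError(Exception):
    """Base class for package errors."""


class FormatError(LysiphenError, ValueError):
    """Input file does not have the expected columns or dialect."""


class EmptyInputError(LysiphenError, ValueError):
    """No valid rows survived parsing."""


class AlignmentError(LysiphenError, ValueError):
    """Weight and environment streams do not overlap in time."""


class DomainError(LysiphenError, ValueError):
    """Argument outside its physical/physiological domain."""


class PhaseError(LysiphenError, ValueError):
    """Operation requested in an experiment phase where it is undefined."""


class DesignError(LysiphenError, ValueError):
    """Factorial layout or sample design is degenerate."""


class FitError(LysiphenError, RuntimeError):
    """Piecewise fit could not be carried out."""


class DegeneratePartitionError(FitError):
    """A candidate breakpoint leaves fewer than two points on one side."""


class AggregationError(LysiphenError, ValueError):
    """Fewer than two converged replicate fits to aggregate."""


class SimulationError(LysiphenError, RuntimeError):
    """Simulator parameters produced a non-physical state."""
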