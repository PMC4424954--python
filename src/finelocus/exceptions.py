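"""Exception hierarchy for finelocus."""


class FinelocusError(Exception):
    """Base class for all finelocus errors."""


class TableParseError(FinelocusError):
    """A delimited input file could not be parsed (names row/column)."""


class QCError(FinelocusError):
    """A QC filter was requested on records lacking the required field."""


class DegenerateTableError(FinelocusError):
    """A 2x2 table has an all-zero margin or is otherwise untestable."""


class SeparationError(FinelocusError):
    """Complete separation in logistic regression: the MLE diverges."""


class SingularDesignError(FinelocusError):
    """Logistic design matrix is singular (e.g. constant or collinear dosages)."""


class ConvergenceError(FinelocusError):
    """An iterative fit exhausted its iteration budget."""


class SimulationError(FinelocusError):
    """Cohort simulation could not satisfy the request (e.g. infeasible sizes)."""
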