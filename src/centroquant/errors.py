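"""Exception hierarchy shared across the pipeline stages."""


class CentroquantError(Exception):
    """Base class for all package errors."""


class FormatError(CentroquantError):
    """An input file does not match the declared layout (plane counts, dtypes...)."""


class ParameterError(CentroquantError):
    """A configuration value violates its contract."""


class ContractError(CentroquantError):
    """A function precondition was violated by the caller."""


class InputError(CentroquantError):
    """A data input is degenerate or unusable (empty selection, bad polygon...)."""


class PlacementError(CentroquantError):
    """The simulator could not place all cells without overlap."""


class InfeasibleTallyError(CentroquantError):
    """A (cells, peaks) tally admits no per-cell count assignment in {1, 2}."""


class BackendUnavailableError(CentroquantError):
    """The requested segmentation backend is not installed."""


class InsufficientDataError(CentroquantError):
    """Too few cells or groups for the requested statistical fit."""


class ConvergenceError(CentroquantError):
    """An iterative fit failed to converge; carries the optimizer trace."""


class AnnotationError(CentroquantError):
    """Review annotations reference unknown cells or centrosomes."""
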