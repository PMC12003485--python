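"""Exception hierarchy shared across the pipeline."""


class MeromixError(Exception):
    """Base class for all pipeline errors."""


class SchemaError(MeromixError):
    """A required column or field is missing from an input table."""


class ParseError(MeromixError):
    """A cell could not be converted; message names the row and column."""


class InsufficientDataError(MeromixError):
    """Too few rows/samples to perform the operation."""


class DomainError(MeromixError, ValueError):
    """An argument is outside its physically valid range."""


class MissingChannelError(MeromixError):
    """A profile or event table lacks a channel the operation needs."""


class GridError(MeromixError):
    """Depth grids cannot be aligned by interpolation."""


class ScenarioError(MeromixError):
    """A synthetic scenario is internally inconsistent."""


class ParameterError(MeromixError, ValueError):
    """Generator parameters violate their constraints (e.g. simplex sums)."""
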