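"""Exception hierarchy for curvsense.

Every anticipated failure mode raises a subclass of :class:`CurvsenseError`
so callers (and the CLI) can distinguish validation problems (exit code 1)
from runtime failures (exit code 2).
"""


class CurvsenseError(Exception):
    """Base class for all curvsense errors."""


class InvalidConfigError(CurvsenseError, ValueError):
    """A configuration value violates its documented invariant."""


class EmptySelectionError(CurvsenseError, ValueError):
    """A bead/frame selection matched nothing; the message names the selection."""


class EmptyHistogramError(CurvsenseError, ValueError):
    """No data fell inside the histogram range (or no data was given)."""


class FitFailureError(CurvsenseError, RuntimeError):
    """Nonlinear fit did not converge; carries optimizer diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class InvalidInputError(CurvsenseError, ValueError):
    """Numerically invalid input to an analysis routine."""


class DegenerateGeometryError(CurvsenseError, ValueError):
    """Geometry too degenerate to define the requested quantity."""


class ParseError(CurvsenseError, ValueError):
    """A text input file is malformed; carries the offending line number."""

    def __init__(self, message: str, path=None, line: int | None = None):
        super().__init__(message)
        self.path = path
        self.line = line
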