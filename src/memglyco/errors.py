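"""Exception hierarchy shared across the package."""


class MemglycoError(Exception):
    """Base class for all package-specific errors."""


class ParseError(MemglycoError):
    """A structure file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"{message} (line {line_number})"
        super().__init__(message)
        self.line_number = line_number


class StructureError(MemglycoError):
    """Internally inconsistent structure (e.g. atom-count mismatch between models)."""


class SelectionError(MemglycoError):
    """Invalid atom selection: unknown rule, out-of-range or duplicate indices."""


class ConfigError(MemglycoError):
    """Configuration validation failed; carries the full list of problems."""

    def __init__(self, problems):
        self.problems = list(problems)
        super().__init__("; ".join(self.problems))


class InsufficientDataError(MemglycoError):
    """Too few frames/points for the requested statistic."""


class DegenerateGeometryError(MemglycoError):
    """Geometrically degenerate input (collinear points, on-axis exterior point, ...)."""


class IntegrationError(MemglycoError):
    """Numerical integration blew up; carries the step index."""

    def __init__(self, message: str, step: int | None = None):
        if step is not None:
            message = f"{message} (step {step})"
        super().__init__(message)
        self.step = step
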