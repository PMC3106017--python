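"""Exception hierarchy for viascript.

All library errors derive from :class:`ViascriptError` so callers (and the
CLI) can distinguish usage errors from genuine bugs.
"""


class ViascriptError(Exception):
    """Base class for all viascript errors."""


class InvalidInputError(ViascriptError, ValueError):
    """An argument violates a documented precondition."""


class TrajectoryParseError(InvalidInputError):
    """A trajectory CSV could not be parsed; carries the offending row."""

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        if row is not None:
            message = f"{message} (row {row})"
        super().__init__(message)


class InvalidGridError(InvalidInputError):
    """A discretization grid has zero or negative extent."""


class InvalidConfigError(InvalidInputError):
    """A configuration value is out of range or unknown."""


class ViaPointOverflowError(ViascriptError):
    """More via-points were detected than the representation allows (16)."""

    def __init__(self, count: int, limit: int = 16, branch: str | None = None):
        self.count = count
        self.limit = limit
        self.branch = branch
        where = f" in {branch} branch" if branch else ""
        super().__init__(
            f"detected {count} via-points{where}, exceeding the limit of {limit}"
        )


class UnknownLabelError(ViascriptError, KeyError):
    """A letter or writer label is not part of the fitted model."""


class UnreachableError(ViascriptError, ValueError):
    """A workspace point lies outside the arm's reachable annulus."""

    def __init__(self, x: float, y: float, r_min: float, r_max: float,
                 sample_index: int | None = None):
        r = (x * x + y * y) ** 0.5
        self.radius = r
        self.r_min = r_min
        self.r_max = r_max
        self.sample_index = sample_index
        at = f" at sample {sample_index}" if sample_index is not None else ""
        super().__init__(
            f"point ({x:.4g}, {y:.4g}){at} has radius {r:.4g}, outside the "
            f"reachable annulus [{r_min:.4g}, {r_max:.4g}]"
        )


class DegenerateSampleError(ViascriptError):
    """Repeated sampling produced only degenerate via-point sequences."""
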