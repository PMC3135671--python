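"""Exception hierarchy.

Every error raised on purpose by this package derives from
:class:`ConfselError`, so callers can catch one type at pipeline level
while tests discriminate the specific failure.
"""


class ConfselError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(ConfselError, ValueError):
    """A configuration object violates its invariants."""


class PDBFormatError(ConfselError, ValueError):
    """Malformed coordinate file; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class SelectionError(ConfselError, KeyError):
    """An atom descriptor does not resolve to exactly one atom."""


class DegenerateGeometryError(ConfselError, ValueError):
    """Point sets unfit for a rigid superposition (too few / collinear)."""


class AnchorPlacementError(ConfselError, RuntimeError):
    """Anchor could not be chelated to the frame's zinc within the cutoff."""


class ScoreTableError(ConfselError, ValueError):
    """Malformed external score table; names the offending row."""


class InsufficientDataError(ConfselError, ValueError):
    """Too few observations for the requested statistic."""


class NoRetainedFramesError(ConfselError, RuntimeError):
    """Conformational filter removed every frame.

    Biologically meaningful (a receptor whose pocket is never open cannot
    accept the fragment), so the state tallies travel with the error.
    """

    def __init__(self, counts: dict):
        super().__init__(
            "no frames retained after conformational filtering "
            f"(state counts: {dict(counts)})"
        )
        self.counts = dict(counts)


class CensoringError(ConfselError, ValueError):
    """A fold-ratio direction that censored data cannot support."""


class PipelineInputError(ConfselError, ValueError):
    """Missing or inconsistent pipeline inputs (paths, table pairings)."""
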