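"""Exception hierarchy for gazeperim."""


class GazePerimError(Exception):
    """Base class for all gazeperim errors."""


class InvalidGeometryError(GazePerimError):
    """Non-physical geometric input (non-positive distance, size, ...)."""


class InvalidLuminanceError(GazePerimError):
    """Luminance outside the domain of the decibel attenuation scale."""


class GridError(GazePerimError):
    """Invalid test-grid construction or laterality."""


class KrigingError(GazePerimError):
    """Degenerate or unsolvable kriging configuration."""


class ConcordanceError(GazePerimError):
    """Concordance comparison cannot be computed (e.g. empty overlap)."""


class ConfigError(GazePerimError):
    """Malformed run configuration (unknown keys, bad values)."""


class ParseError(GazePerimError):
    """Malformed input file; carries row/column context when available."""

    def __init__(self, message: str, row=None, column=None):
        ctx = []
        if row is not None:
            ctx.append(f"row {row}")
        if column is not None:
            ctx.append(f"column {column!r}")
        if ctx:
            message = f"{message} ({', '.join(ctx)})"
        super().__init__(message)
        self.row = row
        self.column = column
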