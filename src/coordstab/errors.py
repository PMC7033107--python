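"""Exception hierarchy shared across the analysis stages."""


class CoordstabError(Exception):
    """Base class for all package errors."""


class ParameterError(CoordstabError, ValueError):
    """A parameter violates its documented domain."""


class ShapeError(CoordstabError, ValueError):
    """Mismatched lengths / shapes between paired inputs."""


class InsufficientDataError(CoordstabError, ValueError):
    """Not enough samples, cycles or pairs to run the operation."""


class DegenerateInputError(CoordstabError, ValueError):
    """Input is degenerate for the operation (constant signal, zero spread...)."""


class ResolutionError(CoordstabError, ValueError):
    """Spectral resolution too coarse for the requested band."""


class FormatError(CoordstabError, ValueError):
    """Malformed on-disk data (missing columns, NaNs, non-monotone time)."""
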