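"""Typed exceptions shared across the package."""


class EdgeRegError(Exception):
    """Base class for all package errors."""


class ImageIOError(EdgeRegError):
    """An image file could not be read or written."""


class UnsupportedFormatError(ImageIOError):
    """File extension is not one of the supported lossless dialects."""


class LatticeMismatchError(EdgeRegError):
    """Two grids expected on the same voxel lattice differ in shape or geometry."""


class CoverageError(EdgeRegError):
    """A control-point grid does not cover the requested image domain."""


class RegistrationError(EdgeRegError):
    """Optimization failed (e.g. the similarity became non-finite)."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = list(trace) if trace is not None else []
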