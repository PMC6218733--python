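"""Exception hierarchy for nmfseg.

Every failure mode named in the module contracts gets its own class so
callers can catch precisely what they expect.
"""


class NmfsegError(Exception):
    """Base class for all package errors."""


class VolumeFileMissingError(NmfsegError, FileNotFoundError):
    """Requested volume file does not exist."""


class UnsupportedFormatError(NmfsegError, ValueError):
    """File extension / header is not a supported volume format."""


class NonVolumeDataError(NmfsegError, ValueError):
    """File decodes but does not contain a 3D image."""


class InvalidLabelError(NmfsegError, ValueError):
    """Label map contains values outside {0, 1, 2, 3, 4}."""


class EmptyMaskError(NmfsegError, ValueError):
    """An operation requiring at least one masked pixel got an empty mask."""


class NoPairsError(NmfsegError, ValueError):
    """No valid co-occurrence pairs exist in any requested direction."""


class ShapeMismatchError(NmfsegError, ValueError):
    """Arrays that must share a shape do not."""


class DegenerateMatrixError(NmfsegError, ValueError):
    """Feature matrix has no two distinct column directions."""


class MaskOverlapError(NmfsegError, ValueError):
    """Core-compartment masks overlap where they must be disjoint."""


class PhantomGeometryError(NmfsegError, ValueError):
    """Phantom compartment geometry violates the nesting invariants."""
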