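"""Exception hierarchy.

Every rejected input raises a named subclass of :class:`RamanCDError`, so
callers can distinguish a malformed file from a degenerate numerical input.
"""


class RamanCDError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(RamanCDError, ValueError):
    """A domain-type invariant was violated."""


class NonMonotonicAxisError(ValidationError):
    """Wavenumber axis is not strictly increasing."""


class SharedAxisError(ValidationError):
    """Pixels of one hyperspectral map carry different wavenumber axes."""


class ShapeMismatchError(ValidationError):
    """Two grids that must share a pixel raster do not."""


class WindowOutsideAxisError(ValidationError):
    """An integration window does not lie inside the wavenumber axis."""


class SpectrumTooShortError(ValidationError):
    """Spectrum has too few channels for the requested filter."""


class ColorImageError(RamanCDError, ValueError):
    """A color (multi-channel) image was given where grayscale is required."""


class LandmarkFormatError(RamanCDError, ValueError):
    """A landmark CSV row could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        super().__init__(message)
        self.line = line


class DegenerateImageError(RamanCDError, ValueError):
    """Image is constant (or otherwise degenerate) and cannot be thresholded."""


class EmptyClassError(RamanCDError, ValueError):
    """Segmentation produced an empty root class."""


class InsufficientLandmarksError(RamanCDError, ValueError):
    """Too few landmark pairs for the requested transform model."""


class CollinearLandmarksError(InsufficientLandmarksError):
    """Landmark configuration is (near-)collinear; the fit is rank deficient."""


class NonInvertibleTransformError(RamanCDError, ValueError):
    """Estimated transform is singular and cannot be applied."""


class NoBandError(RamanCDError, ValueError):
    """No band rises above the noise floor inside the search window."""


class CalibrationError(RamanCDError, ValueError):
    """Calibration standards are unusable (identical abscissae or zero slope)."""
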