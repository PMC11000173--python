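"""Exception hierarchy shared across the package.

All errors derive from :class:`ChromaroiError` so callers can catch the
package's failures with a single ``except`` clause; the subclasses also
derive from the closest builtin (``ValueError``/``OSError``) so they behave
sensibly for callers that only know the standard library.
"""


class ChromaroiError(Exception):
    """Base class for all chromaroi errors."""


class ImageFormatError(ChromaroiError, ValueError):
    """Raised when an input image is not a 24-bit RGB raster."""


class DomainError(ChromaroiError, ValueError):
    """Raised when an argument lies outside its documented domain."""


class ShapeError(ChromaroiError, ValueError):
    """Raised when array shapes are inconsistent with each other."""


class DegenerateInputError(ChromaroiError, ValueError):
    """Raised when data is constant/rank-deficient in a way that makes the
    requested statistic undefined (zero-variance response, identical samples,
    zero-spread residuals)."""


class ArtifactStateError(ChromaroiError, RuntimeError):
    """Raised when a pipeline stage is invoked before its prerequisites
    (e.g. interval selection without a prior ROI-selection run)."""
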