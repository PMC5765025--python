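"""Exception hierarchy.

Everything raised on purpose by dfclust derives from :class:`DFClustError`
so callers can catch the package's own failures without swallowing
programming errors.  :class:`IllConditionedFitError` is load-bearing: the
model-selection loop uses it as the signal that a candidate cluster number
is no longer estimable and the search must be truncated.
"""


class DFClustError(Exception):
    """Base class for all dfclust errors."""


class InvalidParameterError(DFClustError, ValueError):
    """A parameter is outside its documented range (e.g. D < 1, alpha <= 0)."""


class DomainError(DFClustError, ValueError):
    """An input value is outside the mathematical domain (e.g. negative density)."""


class DimensionMismatchError(DFClustError, ValueError):
    """Arrays that must share a shape or dimensionality do not."""


class DegenerateDensityError(DFClustError, ValueError):
    """The density is degenerate for the requested operation (e.g. <t> = 0)."""


class TooFewPointsError(DFClustError, ValueError):
    """Not enough data points for the requested number of mixture components."""


class IllConditionedFitError(DFClustError, RuntimeError):
    """A mixture fit produced a covariance that is not positive definite.

    Model selection treats this as the truncation signal for the
    cluster-number search.
    """


class NoStationaryPointError(DFClustError, RuntimeError):
    """No quasi-stationary point could be located on the HF curve."""


class SingularDesignError(DFClustError, ValueError):
    """The design matrix of a linear-Gaussian fit is rank deficient."""

    def __init__(self, deficient_columns):
        self.deficient_columns = list(deficient_columns)
        super().__init__(
            f"design matrix is rank deficient in columns {self.deficient_columns}"
        )


class DegenerateImageError(DFClustError, ValueError):
    """An intensity image carries no mass (all pixels zero)."""


class DegenerateCentersError(DFClustError, ValueError):
    """Two cluster centers fall in the same grid cell."""


class DegenerateChannelError(DFClustError, ValueError):
    """A principal color channel is identically zero."""


class FormatError(DFClustError, ValueError):
    """A file could not be parsed as the expected tabular/image format."""
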