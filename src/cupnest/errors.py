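"""Exception hierarchy shared across the package."""


class CupnestError(Exception):
    """Base class for all package-specific errors."""


class InvalidDimensionError(CupnestError, ValueError):
    """A nest dimension is non-positive or otherwise unusable."""


class InconsistentDimensionsError(CupnestError, ValueError):
    """Inner measurements exceed outer ones beyond tolerance."""


class AmbiguousDimensionError(CupnestError, ValueError):
    """A literature dimension tuple cannot be interpreted unambiguously."""


class TreeError(CupnestError, ValueError):
    """A phylogeny violates a structural precondition."""


class TraitError(CupnestError, ValueError):
    """Trait values are missing, constant or otherwise unfit for an estimator."""


class DesignError(CupnestError, ValueError):
    """A model design matrix cannot be assembled as specified."""


class ConvergenceError(CupnestError, RuntimeError):
    """An MCMC or optimisation routine failed a structural requirement."""


class GeoError(CupnestError, ValueError):
    """A geospatial input violates a precondition (missing attribute, empty range)."""
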