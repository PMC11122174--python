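"""Exception types shared across the package."""


class OrbitMorphError(Exception):
    """Base class for all orbitmorph errors."""


class PhantomGeometryError(OrbitMorphError):
    """Phantom geometry invalid or does not fit the requested grid."""


class ThresholdError(OrbitMorphError):
    """No bone/soft-tissue threshold can be derived from the image."""


class SeedError(OrbitMorphError):
    """Segmentation seed placed in bone or outside the growable medium."""


class LeakError(OrbitMorphError):
    """Cavity growth escaped through a wall opening."""


class NonTerminationError(OrbitMorphError):
    """Cavity growth did not converge within the iteration budget."""


class NonWatertightError(OrbitMorphError):
    """Mesh boundary is not closed (an aperture is missing its cap)."""


class DegenerateInputError(OrbitMorphError):
    """Input is degenerate for the requested statistic or measurement."""
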