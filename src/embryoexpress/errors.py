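"""Exception hierarchy.

All domain failures derive from :class:`EmbryoExpressError` so callers can
distinguish scientific/domain errors (exit code 1 in the CLI) from
configuration errors (exit code 2).
"""


class EmbryoExpressError(Exception):
    """Base class for all domain errors raised by this package."""


class InputError(EmbryoExpressError, ValueError):
    """Invalid input values or inconsistent arguments."""


class InvalidDesignError(InputError):
    """A sequence-library design that cannot be realised (e.g. motif longer
    than the sequence it should be embedded in)."""


class GenerationError(EmbryoExpressError):
    """Synthetic-data generation failed (e.g. nucleus packing infeasible)."""


class NoEmbryoError(EmbryoExpressError):
    """No embryo foreground could be found in an image."""


class OrientationError(EmbryoExpressError):
    """Embryo axis orientation is ambiguous or unresolved."""


class PlacementError(EmbryoExpressError):
    """A region of interest does not fit inside the embryo mask."""


class DegenerateNormalizationError(EmbryoExpressError):
    """Profile normalization is impossible because the posterior tail is
    (numerically) flat."""


class DegenerateGeometryError(EmbryoExpressError):
    """Stripe geometry is degenerate (e.g. all member nuclei share one AP
    position)."""


class EmptyRunError(EmbryoExpressError):
    """A pipeline run produced no (or too few) usable embryos."""


class ConfigError(EmbryoExpressError):
    """Invalid run configuration; carries the offending key when known."""

    def __init__(self, message: str, key: str | None = None):
        super().__init__(message)
        self.key = key
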