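"""Exception hierarchy.

Every error raised deliberately by grassnet derives from :class:`GrassnetError`
so pipeline code can distinguish model/configuration problems from bugs.
"""


class GrassnetError(Exception):
    """Base class for all grassnet errors."""


class ConfigurationError(GrassnetError):
    """Invalid configuration (fractions, extents, missing blocks...)."""


class GenerationError(GrassnetError):
    """Synthetic generation failed (infeasible placement or spacing)."""


class ExtractionError(GrassnetError):
    """Covariate extraction failed (site outside extent, bad buffer)."""


class AlignmentError(GrassnetError):
    """Coarse and fine grids are not aligned."""


class NumericError(GrassnetError):
    """Non-finite quantity in a likelihood or simulation."""


class FittingError(GrassnetError):
    """Model fitting failed in a non-recoverable way."""


class PlacementError(GrassnetError):
    """A footprint could not be placed under the given constraints."""


class ScenarioError(GrassnetError):
    """Unknown or inconsistent randomization scenario."""
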