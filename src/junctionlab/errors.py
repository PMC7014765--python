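"""Exception hierarchy shared across junctionlab modules."""


class JunctionLabError(Exception):
    """Base class for all junctionlab errors."""


class FormatError(JunctionLabError):
    """An input file decodes, but not to the shape/dtype this pipeline accepts."""


class ParameterError(JunctionLabError, ValueError):
    """A numeric parameter is outside its valid range."""


class GeometryError(JunctionLabError):
    """A waypoint polygon is degenerate (zero area, self-intersecting, too few vertices)."""


class ShapeError(JunctionLabError):
    """Two arrays/images that must share a shape do not."""


class ConfigError(JunctionLabError):
    """A project configuration is incomplete or inconsistent."""


class GenerationError(JunctionLabError):
    """A synthetic-fixture request is infeasible (e.g. phenotype fractions sum > 1)."""
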