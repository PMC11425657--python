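"""Package exception hierarchy."""


class ModganError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(ModganError, ValueError):
    """A physical or configuration parameter is out of its valid domain."""


class MappingError(ModganError, KeyError):
    """A tissue label has no entry in the supplied uptake table."""


class PlacementError(ModganError, RuntimeError):
    """Random placement (e.g. of lesions) failed within the retry budget."""


class SamplingError(ModganError, RuntimeError):
    """Rejection sampling could not satisfy the requested metric ranges."""


class GeometryError(ModganError, ValueError):
    """A phantom geometry specification is internally inconsistent."""


class ShapeError(ModganError, ValueError):
    """Array arguments have incompatible shapes."""


class ConfigError(ModganError, ValueError):
    """A configuration file or object violates the schema."""


class CheckpointError(ModganError, IOError):
    """Model weights could not be located or do not match the architecture."""


class DegenerateSampleError(ModganError, ValueError):
    """A statistical routine received a degenerate (e.g. constant) sample."""
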