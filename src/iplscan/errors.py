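"""Exception types shared across the package."""


class IplscanError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(IplscanError, ValueError):
    """A physical or model parameter is outside its valid domain."""


class ConfigError(IplscanError, ValueError):
    """A configuration value or combination of values is invalid."""


class PlacementError(IplscanError, RuntimeError):
    """Synthetic ROI footprints could not be placed without overlap."""


class EmptyTraceError(IplscanError, ValueError):
    """An ROI mask yields no usable pixels (e.g. fully inside artefact lines)."""


class UndefinedQualityError(IplscanError, ValueError):
    """Quality index requested with fewer than two repeats."""


class ContainerSchemaError(IplscanError, ValueError):
    """HDF5 container schema version or required group mismatch."""
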