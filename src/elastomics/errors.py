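"""Exception hierarchy shared across the package."""


class ElastomicsError(Exception):
    """Base class for all package errors."""


class ConfigError(ElastomicsError):
    """Invalid configuration (e.g. vmin >= vmax, empty feature bank)."""


class GeometryError(ElastomicsError):
    """Degenerate or out-of-bounds ROI / lesion geometry."""


class ShapeError(ElastomicsError):
    """Mismatched raster dimensions."""


class DomainError(ElastomicsError):
    """Values outside the documented domain of an operation."""


class SchemaError(ElastomicsError):
    """Feature-table columns do not match what a fitted model expects."""


class FeatureExtractionError(ElastomicsError):
    """Texture features requested on an ROI where they are undefined."""
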