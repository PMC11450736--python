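"""Exception types shared across the pipeline stages."""


class SevenError(Exception):
    """Base class for all pipeline errors."""


class ConfigError(SevenError):
    """Invalid parameter value or inconsistent assay configuration."""


class FormatError(SevenError):
    """A delimited-text table does not match the expected schema."""


class DegenerateGeometryError(SevenError):
    """Too few or collinear localizations for a Voronoi tessellation."""
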