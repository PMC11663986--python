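"""Package-level exception types."""


class ConfigurationError(ValueError):
    """A configuration value violates its documented constraints."""


class GeometryError(ValueError):
    """A phantom structure cannot be placed or rasterized on the grid."""


class DataError(ValueError):
    """An input table is incomplete or inconsistent."""
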