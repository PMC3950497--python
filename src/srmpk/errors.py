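"""Exception types shared across the package."""


class SchemaError(ValueError):
    """A tabular input does not conform to the expected column schema."""


class DataError(ValueError):
    """A tabular input is structurally valid but contains bad data."""
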