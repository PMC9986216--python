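"""Exception types shared across the package."""


class FormatError(ValueError):
    """An input file does not conform to the expected tabular layout."""


class ValidationError(ValueError):
    """A parsed value violates its documented domain."""


class SchemaAlignmentError(ValueError):
    """Prediction-time features cannot be aligned to a model's schema."""
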