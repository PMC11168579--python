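"""Exception types shared across the package."""


class SchemaError(ValueError):
    """A tabular input does not match the declared column schema."""


class FormatError(ValueError):
    """A volume file decodes to something other than an integer label grid."""


class DegenerateInputError(RuntimeError):
    """A geometric configuration is too close to degenerate to resolve.

    Raised by the synthetic generators when rejection sampling fails to find
    a generic seed configuration, and by the brute-force Delaunay oracle when
    points are near-cospherical within tolerance.
    """
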