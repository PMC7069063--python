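"""Package-level exception types."""


class ParameterError(ValueError):
    """An argument violates a documented precondition."""


class FormatError(ValueError):
    """An input file could not be parsed into a valid graph."""


class UndefinedMetricError(ValueError):
    """The requested metric is undefined for this graph (e.g. no edges)."""
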