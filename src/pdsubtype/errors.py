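"""Exception hierarchy: validation errors vs. degenerate numerical inputs."""


class PdSubtypeError(Exception):
    """Base class for all package errors."""


class ValidationError(PdSubtypeError):
    """Malformed or contract-violating input (bad schema, bad config, coverage gap)."""


class DegenerateInputError(PdSubtypeError):
    """Structurally valid input on which the statistic is undefined (zero SD, n<2)."""
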