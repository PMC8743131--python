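"""Exception hierarchy.

Three error classes map onto the three failure modes the pipeline
distinguishes (and the CLI exit codes): bad configuration, bad input data,
and numerical failure of an estimator.
"""


class MRPipeError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MRPipeError):
    """A parameter, column mapping, or plan field is invalid."""

    exit_code = 2


class DataError(MRPipeError):
    """Input data violate an invariant (duplicates, zero overlap, sx = 0...)."""

    exit_code = 3


class NumericalError(MRPipeError):
    """An estimator failed to converge or the design is degenerate."""

    exit_code = 4
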