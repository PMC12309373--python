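"""Typed errors raised by the pipeline.

Every parsing or validation failure raises one of these instead of letting a
partial result escape; the CLI maps them onto exit codes (input/consistency/
config errors -> 2, convergence errors -> 3).
"""


class AnchoraError(Exception):
    """Base class for all package errors."""


class InputFormatError(AnchoraError):
    """A file does not conform to its expected dialect (named column/line)."""


class ConsistencyError(AnchoraError):
    """Inputs are individually well-formed but mutually contradictory."""


class ConfigError(AnchoraError):
    """A configuration value violates its documented domain."""


class ConvergenceError(AnchoraError):
    """An iterative procedure exhausted its iteration budget."""
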