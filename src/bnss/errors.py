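"""Exception hierarchy for bnss."""

from __future__ import annotations


class BNSSError(Exception):
    """Base class for all bnss errors."""


class ParseError(BNSSError):
    """Malformed rule-file syntax.

    Parameters
    ----------
    message:
        Human-readable description of the problem.
    line:
        1-based line number in the source text, if known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ValidationError(BNSSError):
    """Structurally invalid network (undefined variable, duplicate node, ...)."""


class UnknownNodeError(BNSSError):
    """A node identifier does not exist in the network."""


class UnresolvedVariableError(BNSSError):
    """A rule references a variable missing from the given assignment."""


class LengthMismatchError(BNSSError):
    """Two state vectors of unequal length were compared."""


class TooLargeError(BNSSError):
    """Network exceeds the exact-enumeration size cap."""


class NotStochasticError(BNSSError):
    """A transition matrix row does not sum to one."""


class InvalidSpecError(BNSSError):
    """A random-network generator specification is invalid."""


class UnsupportedFeatureError(BNSSError):
    """The requested serialization dialect cannot express this network."""
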