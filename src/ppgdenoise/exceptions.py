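"""Exception hierarchy used across the package."""


class PpgError(Exception):
    """Base class for all ppgdenoise errors."""


class ParameterError(PpgError, ValueError):
    """A parameter violates its documented domain (e.g. negative rate)."""


class ContractError(PpgError, ValueError):
    """Inputs violate an interface contract (length/range-tag mismatch)."""


class DegenerateInputError(PpgError, ValueError):
    """The input is formally valid but degenerate (e.g. a constant segment)."""


class FormatError(PpgError, ValueError):
    """A file is structurally wrong for the requested format."""


class ParseError(PpgError, ValueError):
    """A file matched the format but its content could not be parsed."""
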