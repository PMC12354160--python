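"""Package-wide exception types."""


class CtdnaHorizonError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CtdnaHorizonError, ValueError):
    """Invalid scenario / model configuration; message names the field."""


class ParseError(CtdnaHorizonError, ValueError):
    """Malformed input file; message names the file and line."""


class OutOfPanelError(CtdnaHorizonError, KeyError):
    """A variant was queried against a panel region it does not lie in."""


class ContractError(CtdnaHorizonError, ValueError):
    """Arguments violate an operation's precondition (e.g. UID mismatch)."""
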