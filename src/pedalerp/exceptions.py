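"""Exception hierarchy shared across the pipeline stages."""


class PedalErpError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PedalErpError):
    """A parameter or spec object is invalid (bad durations, cutoffs, policies...)."""


class DataError(PedalErpError):
    """The data does not support the requested operation (missing channel, mismatch...)."""


class EmptyInputError(DataError):
    """An operation received zero usable segments/trials."""


class ParseError(PedalErpError):
    """A file could not be parsed; the message names the offending location."""
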