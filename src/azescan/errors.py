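"""Exception hierarchy shared by all stages."""


class AzescanError(Exception):
    """Base class for all package errors."""


class ParameterError(AzescanError, ValueError):
    """A caller-supplied parameter is out of its documented range."""


class ParseError(AzescanError, ValueError):
    """A text input could not be parsed; message names the offending position."""


class DataError(AzescanError, ValueError):
    """Inputs are well-formed but inconsistent (missing ids, empty overlaps...)."""


class FormatError(AzescanError, ValueError):
    """A structured file violates its format contract."""


class SelectionError(AzescanError, ValueError):
    """An atom selection is empty or ambiguous."""
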