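"""Exception hierarchy shared across the pipeline."""


class SoyphenError(Exception):
    """Base class for all pipeline errors."""


class VocParseError(SoyphenError):
    """A PASCAL VOC document is malformed; the message names the element."""


class DataValidationError(SoyphenError):
    """Input data violates a contract (duplicate keys, bad counts, ...)."""


class InconsistentLogError(DataValidationError):
    """A phenology event log implies a negative standing count.

    Carries the first offending date in ``date``.
    """

    def __init__(self, message: str, date=None):
        super().__init__(message)
        self.date = date
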