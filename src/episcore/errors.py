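"""Exception hierarchy shared across the package."""


class EpiscoreError(Exception):
    """Base class for all package-specific errors."""


class BedParseError(EpiscoreError, ValueError):
    """A BED/bedGraph/TSV line could not be parsed; message names the line."""


class DataError(EpiscoreError, ValueError):
    """Input data violate a documented contract (e.g. negative coverage)."""


class ArgumentError(EpiscoreError, ValueError):
    """An argument combination violates a documented precondition."""
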