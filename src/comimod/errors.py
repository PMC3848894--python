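"""Exception hierarchy shared across the package."""


class ComimodError(Exception):
    """Base class for all errors raised by comimod."""


class DataError(ComimodError):
    """Malformed or inconsistent input data."""


class NoModulesSelectedError(ComimodError):
    """No module reached the selection threshold; lower --threshold or inspect the data."""
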