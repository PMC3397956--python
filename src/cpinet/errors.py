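"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: :class:`ConfigurationError` -> 2,
:class:`DataError` -> 3.
"""


class CPINetError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(CPINetError):
    """Invalid options, missing columns, inconsistent parameters."""


class DataError(CPINetError):
    """Problems with the data itself (empty network, duplicate ids, ...)."""
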