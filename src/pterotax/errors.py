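"""Exception hierarchy shared across the package.

The CLI maps :class:`InputError` to exit code 2 and
:class:`NumericalError` to exit code 3.
"""


class PterotaxError(Exception):
    """Base class for all package errors."""


class InputError(PterotaxError):
    """Malformed or inconsistent user input (files, tables, alignments)."""


class ConfigurationError(InputError):
    """Invalid generator or pipeline configuration."""


class NumericalError(PterotaxError):
    """A numerical procedure failed (singular matrix, non-convergence...)."""
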