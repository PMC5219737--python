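"""Exception hierarchy shared across gtbkit.

Three broad classes map onto the CLI's exit codes: usage/configuration
problems (exit 1), data/format problems (exit 2), and domain errors raised
by pure computations on invalid values (also exit 1 when they surface
through the CLI).
"""


class GtbError(Exception):
    """Base class for all gtbkit errors."""


class UsageError(GtbError):
    """The caller asked for something the interface does not offer."""


class ConfigError(GtbError):
    """A registry entry, config file or parameter set is inconsistent."""


class FormatError(GtbError):
    """An input file violates its declared format."""


class DomainError(GtbError, ValueError):
    """A pure computation received a value outside its domain."""
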