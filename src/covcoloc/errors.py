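"""Exception hierarchy.

Configuration problems (bad column maps, bad thresholds) and input problems
(empty tables, no shared variants) are kept distinct so the CLI can map them
to different exit codes.
"""


class CovcolocError(Exception):
    """Base class for all package errors."""


class ConfigError(CovcolocError):
    """A configuration value or mapping is invalid (CLI exit code 2)."""


class InputError(CovcolocError):
    """An input table is malformed, empty or unusable (CLI exit code 3)."""


class NoOverlapError(InputError):
    """Two association tables share no variants after harmonization."""
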