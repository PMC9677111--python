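"""Exception hierarchy shared across germdiv.

Two exit-code classes matter for the CLI: input/format problems (exit 2)
and statistical degeneracies on otherwise well-formed data (exit 3).
"""


class GermdivError(Exception):
    """Base class for all germdiv errors."""


class FormatError(GermdivError):
    """Malformed or domain-violating input (file or in-memory container)."""


class AlignmentError(FormatError):
    """Label sets that must agree across inputs do not."""


class ConfigError(FormatError):
    """Run configuration outside its documented domain."""


class DesignError(GermdivError):
    """Experimental-design violation: unbalanced RCBD, singleton population,
    too few factor levels."""


class DegenerateDataError(GermdivError):
    """A statistic is undefined on the given data (all-missing band,
    zero-variance trait, all-zero distances, ...)."""


#: CLI exit codes
EXIT_OK = 0
EXIT_FORMAT = 2
EXIT_DEGENERATE = 3
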