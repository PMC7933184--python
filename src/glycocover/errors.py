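"""Exception hierarchy.

Every error raised deliberately by this package derives from
:class:`GlycocoverError`, so callers (and the CLI) can distinguish
user/configuration mistakes from analysis-stage failures.
"""


class GlycocoverError(Exception):
    """Base class for all errors raised by glycocover."""


class FormatError(GlycocoverError):
    """A structure or trajectory file does not parse under its named standard."""


class ConfigurationError(GlycocoverError):
    """Invalid configuration: entity maps, missing radii, bad parameter files."""


class TopologyError(GlycocoverError):
    """Trajectory frames are inconsistent with the topology (e.g. atom count)."""


class SelectionError(GlycocoverError):
    """A selection expression is invalid or resolves to something disallowed."""


class AnalysisError(GlycocoverError):
    """An analysis operation was called with inputs that make it meaningless."""


class ParameterError(GlycocoverError):
    """A numeric parameter is outside its valid range."""


class GenerationError(GlycocoverError):
    """The synthetic generator was asked for a geometrically infeasible scenario."""
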