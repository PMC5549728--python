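"""Exception hierarchy for habind.

Exit-code mapping used by the CLI: ConfigError -> 2, data/format/topology
errors -> 3, ConvergenceError -> 4.
"""


class HabindError(Exception):
    """Base class for all habind errors."""


class FormatError(HabindError):
    """A file could not be parsed in the expected format."""


class TopologyError(HabindError):
    """Structure/trajectory mismatch (atom counts, missing atoms)."""


class SelectionError(HabindError):
    """An atom selection resolved to nothing or is inconsistent."""


class SchemaError(HabindError):
    """Tables/series with incompatible residue sets or shapes."""


class CompositionError(HabindError):
    """Polymer chain does not alternate GlcUA/GlcNAc as required."""


class ConfigError(HabindError):
    """Invalid run or system configuration."""


class DataError(HabindError):
    """Input data violates a documented invariant (e.g. negative counts)."""


class CoverageError(HabindError):
    """Umbrella windows leave a gap along the reaction coordinate."""


class GridRangeError(HabindError):
    """A coordinate, window or partition point lies outside the grid."""


class ConvergenceError(HabindError):
    """Iterative solver failed to reach tolerance within max iterations."""


class GeometryError(HabindError):
    """Ill-formed initial geometry (overlapping beads, bad box)."""


class StabilityError(HabindError):
    """Numerical blow-up during integration."""
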