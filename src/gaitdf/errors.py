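"""Exception hierarchy for the gait-analysis pipeline.

Every stage raises a subclass of :class:`GaitError`, so callers (notably the
CLI) can map failures to exit codes without string matching.
"""


class GaitError(Exception):
    """Base class for all pipeline errors."""


class SchemaError(GaitError):
    """An input table is missing a required column."""


class ParseError(GaitError):
    """A cell could not be parsed (e.g. non-numeric coordinate)."""


class ValidationError(GaitError):
    """Data violate a structural invariant (ordering, overlap, duplicates)."""


class DegenerateConfigurationError(GaitError):
    """Calibration points are collinear or otherwise unusable."""


class ArityError(GaitError):
    """Wrong number of calibration correspondences."""


class ProjectiveInfinityError(GaitError):
    """A point maps to (or numerically near) the line at infinity."""


class NumericError(GaitError):
    """A matrix is singular or an algorithm lost precision."""


class RangeError(GaitError):
    """A step interval lies outside its track."""


class StepExcludedError(GaitError):
    """A step was dropped by a quality rule (e.g. annotation gap too long)."""


class InsufficientDataError(GaitError):
    """Too few samples, curves, animals or groups for the operation."""


class StratificationError(GaitError):
    """Curves from different (side, joint, day) strata were mixed."""


class UnitError(GaitError):
    """Curves or points carry incompatible unit tags."""


class ShapeError(GaitError):
    """Bin counts or array shapes do not match."""


class ConfigError(GaitError):
    """A run configuration parameter is out of its documented range."""
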