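"""Typed exceptions raised across the package."""


class GGNQuantError(Exception):
    """Base class for all package errors."""


class ShapeMismatchError(GGNQuantError):
    """Mask and volume grids do not have the same shape."""


class EmptyMaskError(GGNQuantError):
    """A nodule mask contains no voxels."""


class InvalidVolumeError(GGNQuantError):
    """A CT volume violates its contract (HU range, spacing, finiteness)."""


class DegenerateSampleError(GGNQuantError):
    """An HU sample is too small or too degenerate for the requested statistic."""


class SpecificationError(GGNQuantError):
    """A phantom or cohort specification violates its invariants."""


class SeparationError(GGNQuantError):
    """Logistic regression encountered (quasi-)perfect separation."""


class MissingFeatureError(GGNQuantError):
    """A required feature column is absent from a table."""


class StageError(GGNQuantError):
    """A pipeline stage failed; the message names the stage."""
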