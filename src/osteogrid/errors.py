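"""Exception hierarchy for the whole-bone morphometry pipeline."""


class OsteogridError(Exception):
    """Base class for all package errors."""


class ValidationError(OsteogridError, ValueError):
    """An input violates a documented precondition."""


class RaggedStackError(ValidationError):
    """Slices of an image stack disagree in shape or dtype."""


class BorderContactError(ValidationError):
    """Bone touches the lattice border, so the enclosed volume is undefined."""


class DegenerateClusteringError(OsteogridError):
    """Intensity clustering cannot separate two classes (constant volume)."""


class UndefinedMeasureError(OsteogridError):
    """A morphometric measure is undefined on the given region (e.g. empty)."""


class DegenerateSpecimenError(OsteogridError):
    """A specimen cannot be compartmentalised (no endosteal region, no valid
    grid nodes, ...).  Pipelines record these specimens as excluded rather
    than aborting the cohort, mirroring how porosity-compromised specimens
    are dropped from comparative samples."""
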