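"""Exception hierarchy for retimorph."""


class RetimorphError(Exception):
    """Base class for all retimorph-specific errors."""


class MaskFormatError(RetimorphError):
    """Raster decoded but is not a usable mask (zero area, wrong ndim, ...)."""


class BoundsError(RetimorphError):
    """An ROI window does not fit inside the source image."""


class SchemaError(RetimorphError):
    """A manifest file is missing required columns."""


class ManifestValidationError(RetimorphError):
    """A manifest row carries invalid content (unknown group, duplicate path)."""


class ConfigurationError(RetimorphError):
    """Analysis settings leave too few usable scales or are inconsistent."""


class DegenerateInputError(RetimorphError):
    """The mask is empty or too sparse for the requested analysis."""


class StructureError(RetimorphError):
    """A vessel tree is not a forest (cycle, or multiple parents per node)."""


class DesignError(RetimorphError):
    """A statistical design requirement is violated (missing cell/level)."""
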