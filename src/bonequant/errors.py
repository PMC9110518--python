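"""Exception hierarchy for bonequant.

Every error raised by the package derives from :class:`BoneQuantError` so
callers (and the CLI) can catch pipeline failures in one place.
"""


class BoneQuantError(Exception):
    """Base class for all bonequant errors."""


class FormatError(BoneQuantError):
    """A file could not be parsed as the expected format."""


class GeometryError(BoneQuantError):
    """Volume/mask/region geometry is invalid or inconsistent."""


class MetadataError(BoneQuantError):
    """Acquisition metadata is missing or invalid."""


class UnitsError(BoneQuantError):
    """An operation received a volume in the wrong units."""


class SegmentationError(BoneQuantError):
    """Threshold segmentation produced no usable VOI."""


class InputError(BoneQuantError):
    """Invalid input to a computation (empty VOI, bad metric name, ...)."""
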