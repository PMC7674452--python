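"""Exception hierarchy for dropletquant."""


class DropletQuantError(Exception):
    """Base class for all package errors."""


class FormatError(DropletQuantError):
    """Input file is unreadable or not a grayscale TIFF."""


class ChannelError(FormatError):
    """Multichannel image supplied without a channel selector."""


class DimensionError(DropletQuantError):
    """Mask or image dimensions do not match the stack."""


class DegenerateHistogramError(DropletQuantError):
    """Histogram has fewer than two populated bins; no threshold exists."""


class DelineationError(DropletQuantError):
    """Automatic ROI delineation produced an empty mask and fallback is off."""


class NormalizationError(DropletQuantError):
    """Control group mean is zero or control group is empty."""


class SpecError(DropletQuantError):
    """Synthetic-stack specification is internally inconsistent."""
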