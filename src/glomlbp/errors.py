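"""Exception hierarchy shared across the package."""


class GlomLBPError(Exception):
    """Base class for all package-specific errors."""


class RegionTooSmallError(GlomLBPError):
    """An image region is too small to host a single LBP neighborhood."""


class NeighborhoodOutOfBoundsError(GlomLBPError):
    """A requested LBP center's circular neighborhood leaves the image."""


class DegenerateScoreMapError(GlomLBPError):
    """A score map is constant and cannot be min-max normalized."""


class PlacementError(GlomLBPError):
    """Synthetic disk placement exceeded its retry budget."""


class ConfigError(GlomLBPError):
    """An invalid configuration value."""


class FormatError(GlomLBPError):
    """An unreadable or unsupported input file."""
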