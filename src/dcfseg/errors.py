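"""Exception types shared across the package."""


class DcfsegError(Exception):
    """Base class for package-specific failures."""


class FormatError(DcfsegError, ValueError):
    """An input file is readable but not in a supported image format."""


class BoundsError(DcfsegError, ValueError):
    """A region of interest or coordinate falls outside the image."""


class UnitsError(DcfsegError, ValueError):
    """Physical units (cm per pixel) are required but unavailable."""
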