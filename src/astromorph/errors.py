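"""Exception types raised across the pipeline."""


class AstromorphError(Exception):
    """Base class for all package-specific errors."""


class CanvasOverflowError(AstromorphError):
    """A phantom does not fit on the requested canvas."""


class PlacementError(AstromorphError):
    """Cells could not be placed on a field under the separation constraint."""


class NoSignalError(AstromorphError):
    """Segmentation produced an empty foreground."""


class SomaSeparationError(AstromorphError):
    """No acceptable soma core could be extracted from the cell mask."""


class ZeroPrimariesError(AstromorphError):
    """A cell has no soma-originating primary process; it must be excluded."""
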