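"""Exception hierarchy.

Every error the pipeline raises deliberately derives from :class:`NetQuantError`
so batch drivers can distinguish expected failure modes (bad input, degenerate
image, impossible calibration) from genuine bugs.
"""


class NetQuantError(Exception):
    """Base class for all netquant errors."""


class ImageFormatError(NetQuantError):
    """Input file is not a supported single-channel grayscale image."""


class DimensionMismatchError(NetQuantError):
    """Two images (or an image and a label map) that must align do not."""


class ChannelMismatchError(NetQuantError):
    """An operation received an image tagged with the wrong channel."""


class ConfigurationError(NetQuantError):
    """Invalid or incomplete segmentation parameters."""


class DegenerateImageError(NetQuantError):
    """An automatic threshold was requested on an image with no contrast."""


class CalibrationError(NetQuantError):
    """No threshold in the dynamic range satisfies the calibration constraint.

    Carries the smallest achievable count of over-cutoff objects so the
    caller can report how far the constraint was missed.
    """

    def __init__(self, smallest_achievable_count: int, message: str | None = None):
        self.smallest_achievable_count = smallest_achievable_count
        super().__init__(
            message
            or "no threshold satisfies the calibration constraint; "
            f"smallest achievable large-object count is {smallest_achievable_count}"
        )


class UndefinedRateError(NetQuantError):
    """NET-rate requested for a field with zero nuclei."""


class UnplaceableSceneError(NetQuantError):
    """A synthetic scene could not be placed without forbidden overlap."""


class PairingError(NetQuantError):
    """Channel images could not be paired into complete fields."""
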