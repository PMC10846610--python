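"""Physical calibration of micrographs and image stacks.

All measurements in this package are reported in micrometres and seconds;
:class:`ImageCalibration` is the single place where pixel and frame units
are converted to physical ones.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict


@dataclass(frozen=True)
class ImageCalibration:
    """Physical scaling of an image or image stack.

    Parameters
    ----------
    um_per_px
        Lateral pixel size in micrometres per pixel. Required, strictly positive.
    exposure_s
        Exposure time in seconds for long-exposure stills (streak images).
        May be ``None`` for inputs where it is not needed; operations that
        require it refuse to run without it.
    fps
        Frame rate in frames per second for image stacks / videos. May be
        ``None``; operations that require it refuse to run without it.
    """

    um_per_px: float
    exposure_s: float | None = None
    fps: float | None = None

    def __post_init__(self) -> None:
        if not (self.um_per_px > 0):
            raise ValueError(f"um_per_px must be strictly positive, got {self.um_per_px}")
        if self.exposure_s is not None and not (self.exposure_s > 0):
            raise ValueError(f"exposure_s must be strictly positive, got {self.exposure_s}")
        if self.fps is not None and not (self.fps > 0):
            raise ValueError(f"fps must be strictly positive, got {self.fps}")

    def require_exposure(self) -> float:
        """Return ``exposure_s``, raising if it was not provided."""
        if self.exposure_s is None:
            raise ValueError(
                "this operation requires exposure_s in the calibration "
                "(long-exposure still), but none was provided"
            )
        return self.exposure_s

    def require_fps(self) -> float:
        """Return ``fps``, raising if it was not provided."""
        if self.fps is None:
            raise ValueError(
                "this operation requires fps in the calibration (image stack), "
                "but none was provided"
            )
        return self.fps

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ImageCalibration":
        return cls(
            um_per_px=d["um_per_px"],
            exposure_s=d.get("exposure_s"),
            fps=d.get("fps"),
        )
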