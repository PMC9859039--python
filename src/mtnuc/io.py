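"""Image-stack container and TIFF round-tripping.

A :class:`MovieStack` is a single-channel time-lapse with its two pieces of
physical calibration: pixel size (µm/px) and frame interval (s).  Stacks
are written as multi-frame grayscale TIFFs with the calibration embedded as
a JSON ImageDescription, so a stack written by the simulator can be read
back by the analysis pipeline without side-band metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile


@dataclass
class MovieStack:
    """Time-lapse image stack, shape (frames, height, width)."""

    data: np.ndarray
    pixel_size_um: float
    frame_interval_s: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected (T, H, W) stack, got shape {self.data.shape}")
        if not self.pixel_size_um > 0 or not self.frame_interval_s > 0:
            raise ValueError("pixel_size_um and frame_interval_s must be > 0")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_times(self) -> np.ndarray:
        """Acquisition time of each frame in seconds (first frame at t=0)."""
        return np.arange(self.n_frames) * self.frame_interval_s

    @property
    def duration_s(self) -> float:
        return float(self.frame_times[-1]) if self.n_frames else 0.0

    def save(self, path: str | Path) -> None:
        meta = {
            "pixel_size_um": self.pixel_size_um,
            "frame_interval_s": self.frame_interval_s,
        }
        tifffile.imwrite(
            path,
            self.data.astype(np.float32),
            description=json.dumps(meta),
            photometric="minisblack",
        )

    @classmethod
    def load(
        cls,
        path: str | Path,
        pixel_size_um: float | None = None,
        frame_interval_s: float | None = None,
    ) -> "MovieStack":
        """Read a TIFF stack; calibration comes from embedded JSON metadata
        unless overridden explicitly."""
        with tifffile.TiffFile(path) as tif:
            data = tif.asarray()
            desc = tif.pages[0].description or ""
        meta = {}
        try:
            meta = json.loads(desc)
        except (json.JSONDecodeError, TypeError):
            pass
        px = pixel_size_um if pixel_size_um is not None else meta.get("pixel_size_um")
        fi = (
            frame_interval_s
            if frame_interval_s is not None
            else meta.get("frame_interval_s")
        )
        if px is None or fi is None:
            raise ValueError(
                f"{path}: no embedded calibration; pass pixel_size_um and "
                "frame_interval_s explicitly"
            )
        if data.ndim == 2:
            data = data[None]
        return cls(data=data, pixel_size_um=float(px), frame_interval_s=float(fi))
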