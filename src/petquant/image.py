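"""In-memory 4D activity image with geometry and frame timing."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .schedule import FrameSchedule

__all__ = ["DynamicImage"]


@dataclass
class DynamicImage:
    """An activity-concentration volume series.

    ``data`` has axes (x, y, z, frame) and voxel units kBq/ml; the grid is
    isotropic ``voxel_size`` mm, RAS+ with the voxel index scaled by the
    voxel size as world coordinate.  ``decay_corrected`` records whether
    frames were corrected back to injection time (t = 0 of the schedule).
    """

    data: np.ndarray
    voxel_size: float
    schedule: FrameSchedule | None = None
    decay_corrected: bool = True

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=np.float32)
        if data.ndim == 3:
            data = data[..., np.newaxis]
        if data.ndim != 4:
            raise ValueError(f"expected 3D or 4D data, got ndim={data.ndim}")
        self.data = data
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if self.schedule is not None and len(self.schedule) != data.shape[-1]:
            raise ValueError(
                f"schedule has {len(self.schedule)} frames but data has "
                f"{data.shape[-1]}"
            )

    @property
    def n_frames(self) -> int:
        return self.data.shape[-1]

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape[:3]

    def frame(self, i: int) -> np.ndarray:
        return self.data[..., i]
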