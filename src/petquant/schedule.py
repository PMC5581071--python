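"""Frame schedules for dynamic and static acquisitions.

Times are minutes from injection.  The dynamic preset samples the first
two minutes at 1 s to resolve the bolus, then 2-min frames out to 60 min;
the static preset is the single 45–60 min uptake-window frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["FrameSchedule"]

_CONTIG_TOL = 1e-9


@dataclass(frozen=True)
class FrameSchedule:
    """Contiguous, non-overlapping acquisition frames (minutes)."""

    start: np.ndarray
    duration: np.ndarray

    def __post_init__(self) -> None:
        start = np.asarray(self.start, dtype=float)
        duration = np.asarray(self.duration, dtype=float)
        object.__setattr__(self, "start", start)
        object.__setattr__(self, "duration", duration)
        if start.ndim != 1 or start.shape != duration.shape or start.size == 0:
            raise ValueError("start and duration must be equal-length 1-D arrays")
        if np.any(duration <= 0) or start[0] < 0:
            raise ValueError("durations must be positive and start times non-negative")
        gaps = start[1:] - (start[:-1] + duration[:-1])
        if np.any(np.abs(gaps) > _CONTIG_TOL):
            raise ValueError("frames must be contiguous and non-overlapping")

    @classmethod
    def dynamic(cls) -> "FrameSchedule":
        """120 × 1 s frames followed by 29 × 2 min frames (0–60 min)."""
        dur = np.concatenate([np.full(120, 1.0 / 60.0), np.full(29, 2.0)])
        start = np.concatenate([[0.0], np.cumsum(dur)[:-1]])
        return cls(start=start, duration=dur)

    @classmethod
    def static(cls) -> "FrameSchedule":
        """One 15-min frame over the 45–60 min uptake window."""
        return cls(start=np.array([45.0]), duration=np.array([15.0]))

    @classmethod
    def single(cls, start: float, duration: float) -> "FrameSchedule":
        return cls(start=np.array([float(start)]), duration=np.array([float(duration)]))

    @property
    def n_frames(self) -> int:
        return int(self.start.size)

    @property
    def mid(self) -> np.ndarray:
        return self.start + self.duration / 2.0

    @property
    def end(self) -> np.ndarray:
        return self.start + self.duration

    @property
    def total_duration(self) -> float:
        """Scanned time in minutes (sum of frame durations)."""
        return float(self.duration.sum())

    def __len__(self) -> int:
        return self.n_frames

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, FrameSchedule)
            and np.array_equal(self.start, other.start)
            and np.array_equal(self.duration, other.duration)
        )
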