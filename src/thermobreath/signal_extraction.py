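"""Nostril-temperature signal extraction and the sliding analysis buffer.

Each tracked frame contributes one scalar: the minimum calibrated temperature
inside the ROI (the coldest pixel). Inhalation draws cooler ambient air across
the nostril rim and exhalation releases warmer expired air, so the per-frame
ROI minimum oscillates with the breathing cycle. Samples accumulate in a
sliding buffer of about 20 s (capacity ceil(20 * f_cam)), long enough to hold
several breaths at the slow end of the physiological band while staying
responsive.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .errors import OrderingError
from .frame_codec import TemperatureMap

__all__ = ["Sample", "BreathSignal", "extract_min_temperature"]


def _round_half_away(x: float) -> int:
    """Round half away from zero (2.5 -> 3, -2.5 -> -3)."""
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


@dataclass(frozen=True)
class Sample:
    """One extracted signal sample."""

    frame_index: int
    t_min: float  # degC
    pixel: tuple[int, int]  # (x, y) of the coldest pixel
    roi_area: int  # pixels^2 of the clipped integer ROI


def extract_min_temperature(
    tmap: TemperatureMap,
    roi: tuple[float, float, float, float],
    percentile: float = 0.0,
) -> Optional[tuple[float, tuple[int, int], int]]:
    """Minimum temperature over the inclusive integer pixel set of the ROI.

    Real-valued tracker corners are rounded half-away-from-zero, then clipped
    to the frame; the ROI covers all integer pixels with x1 <= x <= x2 and
    y1 <= y <= y2. Ties break to the first pixel in row-major order. Returns
    ``(t_min, (x, y), roi_area)``, or None when the clipped intersection is
    empty (no sample this frame).

    ``percentile`` > 0 swaps the strict minimum for a low percentile of the
    ROI values (a robust variant guarding dead pixels); the reported pixel is
    still the argmin. Off by default: the raw minimum is the method.
    """
    h, w = tmap.shape
    x1 = max(_round_half_away(roi[0]), 0)
    y1 = max(_round_half_away(roi[1]), 0)
    x2 = min(_round_half_away(roi[2]), w - 1)
    y2 = min(_round_half_away(roi[3]), h - 1)
    if x1 > x2 or y1 > y2:
        return None
    patch = tmap.values[y1 : y2 + 1, x1 : x2 + 1]
    flat = int(np.argmin(patch))
    dy, dx = divmod(flat, patch.shape[1])
    if percentile > 0.0:
        t_min = float(np.percentile(patch, percentile))
    else:
        t_min = float(patch[dy, dx])
    return t_min, (x1 + dx, y1 + dy), patch.size


class BreathSignal:
    """Sliding buffer of extracted nostril temperatures.

    Capacity is ceil(window_s * f_cam) samples (default window 20 s); pushing
    past capacity evicts the oldest sample. Frame indices must be strictly
    increasing.
    """

    def __init__(self, f_cam: float, window_s: float = 20.0) -> None:
        self.f_cam = float(f_cam)
        self.window_s = float(window_s)
        self.capacity = math.ceil(window_s * f_cam)
        self._samples: deque[Sample] = deque(maxlen=self.capacity)

    def push(self, sample: Sample) -> None:
        if self._samples and sample.frame_index <= self._samples[-1].frame_index:
            raise OrderingError(
                f"frame index {sample.frame_index} not after "
                f"{self._samples[-1].frame_index}"
            )
        self._samples.append(sample)

    def __len__(self) -> int:
        return len(self._samples)

    @property
    def samples(self) -> list[Sample]:
        return list(self._samples)

    @property
    def values(self) -> np.ndarray:
        return np.array([s.t_min for s in self._samples], dtype=np.float64)

    @property
    def frame_indices(self) -> np.ndarray:
        return np.array([s.frame_index for s in self._samples], dtype=np.int64)

    @property
    def times(self) -> np.ndarray:
        return self.frame_indices / self.f_cam

    @property
    def span_s(self) -> float:
        """Time covered by the buffered samples, in seconds."""
        if len(self._samples) < 2:
            return 0.0
        return float(self.times[-1] - self.times[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame_index": self.frame_indices,
                "time_s": self.times,
                "t_min_c": self.values,
                "px": [s.pixel[0] for s in self._samples],
                "py": [s.pixel[1] for s in self._samples],
                "roi_area": [s.roi_area for s in self._samples],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, f_cam: Optional[float] = None) -> "BreathSignal":
        """Load a signal CSV; f_cam inferred from the time column if omitted."""
        df = pd.read_csv(path)
        if f_cam is None:
            steps = np.diff(df["time_s"].to_numpy())
            f_cam = 1.0 / float(np.median(steps))
        sig = cls(f_cam=f_cam, window_s=max(20.0, len(df) / f_cam + 1.0))
        for row in df.itertuples(index=False):
            px = int(getattr(row, "px", 0))
            py = int(getattr(row, "py", 0))
            area = int(getattr(row, "roi_area", 1))
            sig.push(Sample(int(row.frame_index), float(row.t_min_c), (px, py), area))
        return sig
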