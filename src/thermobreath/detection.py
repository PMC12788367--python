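"""Detector contract, detection schedule and ROI source selection.

The nostril detector runs only on scheduled frames (every ``stride``-th frame,
default stride 2, i.e. even frames), halving detector cost; on the remaining
frames the Kalman tracker supplies the ROI. The detector itself is a pluggable
callable ``detector(k, tmap) -> Detection | None``; for hermetic testing this
module provides :class:`OracleDetector`, which perturbs a known ground-truth
ROI with corner jitter and random misses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np

from .errors import ConfigurationError, InvalidBoxError

__all__ = [
    "Detection",
    "DetectionSchedule",
    "is_detection_frame",
    "select_roi",
    "best_detection",
    "oracle_detect",
    "OracleDetector",
]

Roi = tuple[float, float, float, float]  # (x1, y1, x2, y2)


@dataclass(frozen=True)
class Detection:
    """A single bounding-box detection with confidence in [0, 1]."""

    x1: float
    y1: float
    x2: float
    y2: float
    confidence: float = 1.0

    def __post_init__(self) -> None:
        if self.x2 < self.x1 or self.y2 < self.y1:
            raise InvalidBoxError(
                f"inverted corners: ({self.x1},{self.y1})-({self.x2},{self.y2})"
            )
        if not 0.0 <= self.confidence <= 1.0:
            raise ConfigurationError(
                f"confidence must be in [0,1], got {self.confidence}"
            )

    @property
    def corners(self) -> Roi:
        return (self.x1, self.y1, self.x2, self.y2)


@dataclass(frozen=True)
class DetectionSchedule:
    """Detector cadence: run every ``stride``-th frame of an ``f_cam`` Hz stream."""

    stride: int = 2
    f_cam: float = 25.0

    def __post_init__(self) -> None:
        if self.stride < 1:
            raise ConfigurationError(f"stride must be >= 1, got {self.stride}")
        if self.f_cam <= 0:
            raise ConfigurationError(f"f_cam must be > 0, got {self.f_cam}")

    @property
    def effective_rate(self) -> float:
        """Detector invocation rate in Hz (f_cam / stride)."""
        return self.f_cam / self.stride


def is_detection_frame(k: int, stride: int = 2) -> bool:
    """True iff frame ``k`` is on the detection schedule (k mod stride == 0)."""
    if k < 0:
        raise ConfigurationError(f"frame index must be >= 0, got {k}")
    if stride < 1:
        raise ConfigurationError(f"stride must be >= 1, got {stride}")
    return k % stride == 0


def select_roi(
    k: int,
    detection: Optional[Detection],
    predicted: Optional[Roi],
    stride: int = 2,
) -> tuple[Optional[Roi], str]:
    """Choose the ROI for frame ``k``: detector box on scheduled frames with a
    detection, tracker prediction otherwise.

    Returns ``(roi, source)`` where source is ``"detector"``, ``"tracker"`` or
    ``"none"`` (no detection and no initialized track: the pipeline skips the
    sample for this frame).
    """
    if is_detection_frame(k, stride) and detection is not None:
        return detection.corners, "detector"
    if predicted is not None:
        return predicted, "tracker"
    return None, "none"


def best_detection(
    detections: Sequence[Detection], confidence_min: float = 0.25
) -> Optional[Detection]:
    """Keep the highest-confidence detection above the threshold, if any."""
    kept = [d for d in detections if d.confidence >= confidence_min]
    if not kept:
        return None
    return max(kept, key=lambda d: d.confidence)


def oracle_detect(
    truth_roi: Roi,
    frame_shape: tuple[int, int],
    jitter_px: float,
    miss_rate: float,
    rng: np.random.Generator,
    confidence: float = 1.0,
) -> Optional[Detection]:
    """Perturb a ground-truth ROI into a synthetic detection.

    With probability ``miss_rate`` returns None; otherwise each corner is
    shifted by an independent uniform offset in [-jitter_px, jitter_px] and the
    box is clipped to the frame. Deterministic given the generator state.
    """
    if not 0.0 <= miss_rate < 1.0:
        raise ConfigurationError(f"miss_rate must be in [0,1), got {miss_rate}")
    if rng.uniform() < miss_rate:
        return None
    h, w = frame_shape
    x1, y1, x2, y2 = truth_roi
    if jitter_px > 0:
        dx1, dy1, dx2, dy2 = rng.uniform(-jitter_px, jitter_px, size=4)
        x1, y1, x2, y2 = x1 + dx1, y1 + dy1, x2 + dx2, y2 + dy2
    x1 = float(np.clip(x1, 0, w - 1))
    x2 = float(np.clip(x2, 0, w - 1))
    y1 = float(np.clip(y1, 0, h - 1))
    y2 = float(np.clip(y2, 0, h - 1))
    if x2 < x1:
        x1, x2 = x2, x1
    if y2 < y1:
        y1, y2 = y2, y1
    return Detection(x1, y1, x2, y2, confidence=confidence)


class OracleDetector:
    """Test-double detector replaying jittered ground-truth ROIs.

    Stands behind the same callable contract as a trained-model adapter:
    ``detector(k, tmap) -> Detection | None``. Tracks how many times it was
    invoked so schedule accounting can be asserted.
    """

    def __init__(
        self,
        truth_rois: np.ndarray,
        frame_shape: tuple[int, int],
        jitter_px: float = 0.0,
        miss_rate: float = 0.0,
        seed: int = 0,
    ) -> None:
        self.truth_rois = np.asarray(truth_rois, dtype=np.float64)
        self.frame_shape = frame_shape
        self.jitter_px = float(jitter_px)
        self.miss_rate = float(miss_rate)
        self.rng = np.random.default_rng(seed)
        self.calls = 0

    def __call__(self, k: int, tmap=None) -> Optional[Detection]:
        self.calls += 1
        roi = tuple(self.truth_rois[k])
        return oracle_detect(
            roi, self.frame_shape, self.jitter_px, self.miss_rate, self.rng
        )
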