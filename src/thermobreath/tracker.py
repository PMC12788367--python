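"""Constant-velocity Kalman tracking of the nostril bounding box.

The state is the 8-vector x = (cx, cy, w, h, cx', cy', w', h'): box center,
size, and their time derivatives (pixels and pixels/s). Dynamics follow the
discrete constant-velocity model

    x_k = F x_{k-1} + w_{k-1},   F = [[I4, dt*I4], [0, I4]],

with white-acceleration process noise Q and a fixed measurement covariance
R. The measurement is the box itself, z = (cx, cy, w, h) = H x with
H = [I4 | 0]. Prediction runs on every frame; the update runs only on
scheduled frames that produced a detection, so the tracker coasts through
skipped frames and short dropouts. All eigenvalues of F are 1 (marginally
stable, as expected for constant velocity) and the pair (F, H) is observable,
so velocities are inferable from box measurements alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .detection import Detection, Roi, is_detection_frame
from .errors import ConfigurationError, InvalidBoxError, UsageError

__all__ = [
    "KalmanConfig",
    "TrackState",
    "transition_matrix",
    "measurement_matrix",
    "process_noise",
    "bbox_to_measurement",
    "state_to_bbox",
    "init_track",
    "predict",
    "update",
    "track_step",
    "KalmanTracker",
]


@dataclass(frozen=True)
class KalmanConfig:
    """Tracker tuning.

    dt is the frame interval 1/f_cam (s). q_scale sets the white-acceleration
    process-noise intensity (px^2/s^3 equivalent); r_scale the per-axis
    measurement variance (px^2). After ``max_coast_frames`` consecutive frames
    without an update the track is declared stale and re-initialized by the
    next detection. Initial covariance is diagonal with ``init_pos_std`` px on
    position/size and ``init_vel_std`` px/s on velocities.
    """

    dt: float = 1.0 / 25.0
    q_scale: float = 1.0
    r_scale: float = 4.0
    max_coast_frames: int = 25
    init_pos_std: float = 10.0
    init_vel_std: float = 25.0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ConfigurationError(f"dt must be > 0, got {self.dt}")
        if self.q_scale <= 0 or self.r_scale <= 0:
            raise ConfigurationError(
                f"q_scale and r_scale must be > 0, got {self.q_scale}, {self.r_scale}"
            )
        if self.max_coast_frames < 1:
            raise ConfigurationError(
                f"max_coast_frames must be >= 1, got {self.max_coast_frames}"
            )


@dataclass
class TrackState:
    """Kalman state: 8-vector estimate, 8x8 covariance, bookkeeping flags."""

    x: np.ndarray
    P: np.ndarray
    initialized: bool = True
    frames_since_update: int = 0

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=np.float64).reshape(8)
        self.P = np.asarray(self.P, dtype=np.float64).reshape(8, 8)


def transition_matrix(dt: float) -> np.ndarray:
    """F = [[I4, dt*I4], [0, I4]]."""
    F = np.eye(8)
    F[:4, 4:] = dt * np.eye(4)
    return F


def measurement_matrix() -> np.ndarray:
    """H = [I4 | 0]: the box (center, size) is observed directly."""
    return np.hstack([np.eye(4), np.zeros((4, 4))])


def process_noise(dt: float, q_scale: float) -> np.ndarray:
    """Discretized white-acceleration noise, independently per box coordinate.

    Each (position, velocity) pair gets the standard 2x2 block
    q * [[dt^4/4, dt^3/2], [dt^3/2, dt^2]].
    """
    Q = np.zeros((8, 8))
    for i in range(4):
        Q[i, i] = q_scale * dt**4 / 4.0
        Q[i, i + 4] = Q[i + 4, i] = q_scale * dt**3 / 2.0
        Q[i + 4, i + 4] = q_scale * dt**2
    return Q


def measurement_noise(r_scale: float) -> np.ndarray:
    return r_scale * np.eye(4)


def bbox_to_measurement(det: Detection | Roi) -> np.ndarray:
    """Corners (x1, y1, x2, y2) -> measurement (cx, cy, w, h)."""
    if isinstance(det, Detection):
        x1, y1, x2, y2 = det.corners
    else:
        x1, y1, x2, y2 = det
    if x2 < x1 or y2 < y1:
        raise InvalidBoxError(f"inverted corners: ({x1},{y1})-({x2},{y2})")
    return np.array(
        [(x1 + x2) / 2.0, (y1 + y2) / 2.0, x2 - x1, y2 - y1], dtype=np.float64
    )


def state_to_bbox(
    state: TrackState, frame_shape: Optional[tuple[int, int]] = None
) -> Roi:
    """Reconstruct corners (cx - w/2, cy - h/2, cx + w/2, cy + h/2).

    Negative estimated sizes are clamped to zero; with ``frame_shape`` given
    the corners are additionally clipped to the frame for downstream use.
    """
    if not state.initialized:
        raise UsageError("cannot reconstruct a box from an uninitialized track")
    cx, cy, w, h = state.x[:4]
    w, h = max(w, 0.0), max(h, 0.0)
    x1, y1, x2, y2 = cx - w / 2.0, cy - h / 2.0, cx + w / 2.0, cy + h / 2.0
    if frame_shape is not None:
        fh, fw = frame_shape
        x1, x2 = np.clip([x1, x2], 0, fw - 1)
        y1, y2 = np.clip([y1, y2], 0, fh - 1)
    return (float(x1), float(y1), float(x2), float(y2))


def init_track(z: np.ndarray, cfg: KalmanConfig) -> TrackState:
    """Start a track from a first measurement: positions from z, zero velocities."""
    x = np.zeros(8)
    x[:4] = z
    P = np.diag(
        [cfg.init_pos_std**2] * 4 + [cfg.init_vel_std**2] * 4
    ).astype(np.float64)
    return TrackState(x=x, P=P, initialized=True, frames_since_update=0)


def predict(state: TrackState, cfg: KalmanConfig) -> TrackState:
    """Time update: x <- F x, P <- F P F' + Q."""
    if not state.initialized:
        raise UsageError("predict called on an uninitialized track")
    F = transition_matrix(cfg.dt)
    Q = process_noise(cfg.dt, cfg.q_scale)
    x = F @ state.x
    P = F @ state.P @ F.T + Q
    P = 0.5 * (P + P.T)
    return TrackState(
        x=x, P=P, initialized=True, frames_since_update=state.frames_since_update
    )


def update(state: TrackState, z: np.ndarray, cfg: KalmanConfig) -> TrackState:
    """Measurement update with innovation y, gain K, posterior covariance.

    y = z - H x;  S = H P H' + R;  K = P H' S^-1;
    x <- x + K y;  P <- (I - K H) P   (then symmetrized).
    """
    if not state.initialized:
        raise UsageError("update called on an uninitialized track")
    H = measurement_matrix()
    R = measurement_noise(cfg.r_scale)
    z = np.asarray(z, dtype=np.float64).reshape(4)
    y = z - H @ state.x
    S = H @ state.P @ H.T + R
    try:
        K = state.P @ H.T @ np.linalg.inv(S)
    except np.linalg.LinAlgError as exc:  # cannot occur with r_scale > 0
        raise ArithmeticError("singular innovation covariance") from exc
    x = state.x + K @ y
    P = (np.eye(8) - K @ H) @ state.P
    P = 0.5 * (P + P.T)
    return TrackState(x=x, P=P, initialized=True, frames_since_update=0)


def track_step(
    state: Optional[TrackState],
    k: int,
    detection: Optional[Detection],
    cfg: KalmanConfig,
    stride: int = 2,
    frame_shape: Optional[tuple[int, int]] = None,
) -> tuple[Optional[TrackState], Optional[Roi], int]:
    """Advance the tracker by one frame.

    Predict always (once initialized); update iff frame ``k`` is scheduled AND
    a detection exists (the measurement-use indicator m_k). The first scheduled
    detection initializes the state with zero velocities. After
    ``max_coast_frames`` consecutive misses the track is dropped and the next
    detection re-initializes it.

    Returns ``(state, roi, m_k)``; roi is None while no track exists.
    """
    scheduled = is_detection_frame(k, stride)
    usable = scheduled and detection is not None

    if state is None or not state.initialized:
        if usable:
            new = init_track(bbox_to_measurement(detection), cfg)
            return new, state_to_bbox(new, frame_shape), 1
        return state, None, 0

    new = predict(state, cfg)
    if usable:
        new = update(new, bbox_to_measurement(detection), cfg)
        m_k = 1
    else:
        new = replace(new, frames_since_update=new.frames_since_update + 1)
        m_k = 0
        if new.frames_since_update > cfg.max_coast_frames:
            new = replace(new, initialized=False)
            return new, None, 0
    return new, state_to_bbox(new, frame_shape), m_k


class KalmanTracker:
    """Stateful wrapper around :func:`track_step` for frame-by-frame streaming."""

    def __init__(
        self,
        cfg: KalmanConfig,
        stride: int = 2,
        frame_shape: Optional[tuple[int, int]] = None,
    ) -> None:
        self.cfg = cfg
        self.stride = stride
        self.frame_shape = frame_shape
        self.state: Optional[TrackState] = None

    def step(
        self, k: int, detection: Optional[Detection]
    ) -> tuple[Optional[Roi], int]:
        self.state, roi, m_k = track_step(
            self.state, k, detection, self.cfg, self.stride, self.frame_shape
        )
        return roi, m_k

    @property
    def predicted_roi(self) -> Optional[Roi]:
        if self.state is None or not self.state.initialized:
            return None
        return state_to_bbox(self.state, self.frame_shape)
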