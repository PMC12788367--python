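"""Ground-truthed synthetic breathing signals and thermal video rendering.

The nostril-temperature signal is modeled as a quasi-periodic process

    T(t) = T0 + A * sin(2*pi*f_RR*t + phi) + d_low(t) + n_high(t)

with baseline T0, oscillation amplitude A, respiratory frequency f_RR, slow
drift d_low (a slow sinusoid standing in for posture/ambient trends) and
white high-frequency noise n_high. Ground-truth phase is the sign of the
noiseless oscillation derivative: warming = exhalation (+1), cooling =
inhalation (-1); the drift term is excluded from the truth so labels refer to
the breath, not the trend.

``render_synthetic_video`` paints each sample into a radiometric frame —
ambient background, warm face ellipse, cold circular nostril blob whose
minimum equals the signal sample — so the entire pipeline (codec, detection,
tracking, extraction, phase, rate) is testable hermetically with exact ground
truth. ``paced_protocol`` concatenates phase-continuous blocks at stepped
target rates, emulating a metronome-paced breathing session.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .errors import ConfigurationError, SceneError
from .frame_codec import RawFrame, TemperatureMap, encode_raw_frame

__all__ = [
    "SyntheticBreathParams",
    "SceneParams",
    "BreathTruth",
    "ProtocolData",
    "simulate_breath_signal",
    "render_synthetic_video",
    "paced_protocol",
]


@dataclass(frozen=True)
class SyntheticBreathParams:
    """Signal-model parameters (defaults: plausible nostril magnitudes).

    t0 : baseline temperature, degC.
    amplitude : breathing oscillation amplitude A, degC.
    f_rr : respiratory frequency, Hz (0.2 Hz = 12 BPM).
    phase : oscillation phase at t=0, rad.
    drift_amp / drift_period : slow-drift sinusoid, degC / s.
    noise_sd : white noise standard deviation, degC.
    f_cam : sampling (camera) rate, Hz.
    duration : signal length, s.
    seed : RNG seed; identical seeds give identical sequences.
    """

    t0: float = 29.0
    amplitude: float = 1.5
    f_rr: float = 0.3
    phase: float = 0.0
    drift_amp: float = 0.3
    drift_period: float = 120.0
    noise_sd: float = 0.15
    f_cam: float = 25.0
    duration: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.amplitude < 0 or self.noise_sd < 0 or self.drift_amp < 0:
            raise ConfigurationError("amplitude, noise_sd, drift_amp must be >= 0")
        if self.f_cam <= 2 * self.f_rr:
            raise ConfigurationError(
                f"f_cam={self.f_cam} Hz must exceed 2*f_rr={2 * self.f_rr} Hz"
            )
        if self.duration <= 0:
            raise ConfigurationError("duration must be > 0")


@dataclass
class BreathTruth:
    """A simulated signal with its ground truth."""

    samples: np.ndarray  # degC
    times: np.ndarray  # s
    phase_truth: np.ndarray  # +1 exhale / -1 inhale per sample
    rr_true: float  # BPM
    params: SyntheticBreathParams


def simulate_breath_signal(params: SyntheticBreathParams) -> BreathTruth:
    """Sample the signal model at f_cam for the requested duration."""
    n = int(round(params.duration * params.f_cam))
    t = np.arange(n) / params.f_cam
    arg = 2 * np.pi * params.f_rr * t + params.phase
    breath = params.amplitude * np.sin(arg)
    drift = (
        params.drift_amp * np.sin(2 * np.pi * t / params.drift_period)
        if params.drift_amp > 0
        else 0.0
    )
    rng = np.random.default_rng(params.seed)
    noise = rng.normal(0.0, params.noise_sd, size=n) if params.noise_sd > 0 else 0.0
    samples = params.t0 + breath + drift + noise
    # warming (d/dt > 0) <-> exhalation: derivative of A sin(.) has cos sign
    phase_truth = np.where(np.cos(arg) >= 0, 1, -1).astype(np.int8)
    return BreathTruth(
        samples=samples,
        times=t,
        phase_truth=phase_truth,
        rr_true=params.f_rr * 60.0,
        params=params,
    )


@dataclass(frozen=True)
class SceneParams:
    """Geometry and temperatures of the rendered thermal scene.

    The face is a warm ellipse on an ambient background; the nostril is a
    cold circular blob inside it whose minimum tracks the breathing signal.
    The ground-truth ROI is the blob's bounding square plus ``roi_margin``.
    The blob center can drift sinusoidally in x to exercise the tracker.
    Display planes are gray-mapped over ``display_range`` degC.
    """

    height: int = 192
    width: int = 256
    face_temp: float = 34.0
    ambient_temp: float = 22.0
    nostril_radius: int = 6
    roi_margin: int = 2
    face_center: Optional[tuple[float, float]] = None  # (x, y)
    face_axes: Optional[tuple[float, float]] = None  # (rx, ry)
    traj_amp_px: float = 0.0
    traj_period_s: float = 8.0
    display_range: tuple[float, float] = (15.0, 40.0)

    def resolved_face(self) -> tuple[tuple[float, float], tuple[float, float]]:
        center = self.face_center or (self.width / 2.0, self.height * 0.45)
        axes = self.face_axes or (self.width * 0.22, self.height * 0.32)
        return center, axes


def _nostril_center(scene: SceneParams, t: float) -> tuple[float, float]:
    (fx, fy), (_, ry) = scene.resolved_face()
    base_x, base_y = fx, fy + 0.45 * ry
    if scene.traj_amp_px > 0:
        base_x = base_x + scene.traj_amp_px * math.sin(
            2 * math.pi * t / scene.traj_period_s
        )
    return base_x, base_y


def _truth_roi(scene: SceneParams, center: tuple[float, float]) -> tuple[float, float, float, float]:
    half = scene.nostril_radius + scene.roi_margin
    cx, cy = center
    return (cx - half, cy - half, cx + half, cy + half)


def render_frame(
    scene: SceneParams, sample: float, t: float, frame_index: int
) -> tuple[RawFrame, tuple[float, float, float, float]]:
    """Render one sample into a raw frame; returns the frame and truth ROI."""
    h, w = scene.height, scene.width
    (fx, fy), (rx, ry) = scene.resolved_face()
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)

    values = np.full((h, w), scene.ambient_temp)
    face = ((xx - fx) / rx) ** 2 + ((yy - fy) / ry) ** 2 <= 1.0
    values[face] = scene.face_temp

    cx, cy = _nostril_center(scene, t)
    px, py = int(round(cx)), int(round(cy))
    r = scene.nostril_radius
    roi = _truth_roi(scene, (cx, cy))
    if roi[0] < 0 or roi[1] < 0 or roi[2] > w - 1 or roi[3] > h - 1:
        raise SceneError(f"nostril ROI {roi} leaves the {h}x{w} frame at t={t:.2f}s")
    if sample >= scene.face_temp:
        raise SceneError(
            f"signal sample {sample} degC not below face {scene.face_temp} degC"
        )
    # Parabolic cold well: exactly `sample` at the center pixel, warming
    # toward (but staying below) face temperature at the rim.
    dist2 = (xx - px) ** 2 + (yy - py) ** 2
    blob = dist2 <= r * r
    values[blob] = sample + 0.8 * (scene.face_temp - sample) * dist2[blob] / (r * r)
    values[py, px] = sample
    if not np.all(face[blob]):
        raise SceneError("nostril blob extends beyond the face ellipse")

    lo, hi = scene.display_range
    image_plane = np.clip((values - lo) / (hi - lo) * 255.0, 0, 255).astype(np.uint8)
    tmap = TemperatureMap(values)
    frame = encode_raw_frame(tmap, image_plane, frame_index=frame_index)
    return frame, roi


def render_synthetic_video(
    truth: BreathTruth, scene: SceneParams = SceneParams()
) -> tuple[list[RawFrame], np.ndarray]:
    """Render a full signal into a frame stream.

    Returns ``(frames, truth_rois)`` with one ROI row (x1, y1, x2, y2) per
    frame. The ROI minimum of frame k equals ``truth.samples[k]`` up to the
    1/64 K encode quantization, and the frame maximum lies on the face, never
    in the nostril.
    """
    frames: list[RawFrame] = []
    rois = np.empty((truth.samples.size, 4))
    for k, (s, t) in enumerate(zip(truth.samples, truth.times)):
        frame, roi = render_frame(scene, float(s), float(t), k)
        frames.append(frame)
        rois[k] = roi
    return frames, rois


@dataclass
class ProtocolData:
    """Concatenated paced-breathing blocks with stepwise ground truth."""

    samples: np.ndarray
    times: np.ndarray
    phase_truth: np.ndarray
    block_id: np.ndarray  # per-sample block index
    rates: np.ndarray  # BPM per block
    boundaries: np.ndarray  # start sample of each block
    f_cam: float

    def block_slice(self, i: int) -> slice:
        start = int(self.boundaries[i])
        stop = (
            int(self.boundaries[i + 1])
            if i + 1 < self.boundaries.size
            else self.samples.size
        )
        return slice(start, stop)


def paced_protocol(
    rates: Sequence[float],
    block_s: float,
    base: SyntheticBreathParams = SyntheticBreathParams(),
    seed: Optional[int] = None,
) -> ProtocolData:
    """Simulate a guided-breathing session of stepped target rates.

    Each block runs ``block_s`` seconds at its rate; the oscillation phase is
    carried across block boundaries so the signal stays continuous. Drift and
    noise follow the base parameters; the seed (default: base seed) fixes the
    noise stream.
    """
    for r in rates:
        if not 5.0 <= r <= 42.0:
            raise ConfigurationError(f"rate {r} BPM outside the 5-42 band")
    f_cam = base.f_cam
    n_block = int(round(block_s * f_cam))
    rng = np.random.default_rng(base.seed if seed is None else seed)

    chunks, phases, blocks = [], [], []
    phi = base.phase
    for b, rate in enumerate(rates):
        f = rate / 60.0
        t_local = np.arange(n_block) / f_cam
        arg = 2 * np.pi * f * t_local + phi
        chunk = base.amplitude * np.sin(arg)
        chunks.append(chunk)
        phases.append(np.where(np.cos(arg) >= 0, 1, -1).astype(np.int8))
        blocks.append(np.full(n_block, b, dtype=np.int64))
        phi = phi + 2 * np.pi * f * n_block / f_cam  # continuity into next block

    n = n_block * len(rates)
    t = np.arange(n) / f_cam
    drift = (
        base.drift_amp * np.sin(2 * np.pi * t / base.drift_period)
        if base.drift_amp > 0
        else 0.0
    )
    noise = rng.normal(0.0, base.noise_sd, size=n) if base.noise_sd > 0 else 0.0
    samples = base.t0 + np.concatenate(chunks) + drift + noise
    return ProtocolData(
        samples=samples,
        times=t,
        phase_truth=np.concatenate(phases),
        block_id=np.concatenate(blocks),
        rates=np.asarray(rates, dtype=np.float64),
        boundaries=np.arange(len(rates)) * n_block,
        f_cam=f_cam,
    )
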