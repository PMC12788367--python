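"""Breathing-phase detection from the nostril-temperature sequence.

The chain is: zero-phase Butterworth band-pass (0.08-0.7 Hz, covering 5-42
breaths/min) -> moving-average velocity surrogate -> per-sample symmetric
threshold adapted from the median absolute deviation (MAD) of recent
velocities -> dwell-gated hysteresis labeling exhalation (+1), inhalation
(-1) and optionally neutral/hold (0) -> consolidation of short A->B->A
flickers into their flanking phase.

The velocity surrogate is the difference of two adjacent length-W moving
averages of the filtered signal,

    v[n] = mean(x[n-W+1..n]) - mean(x[n-2W+1..n-W]),

whose sign follows physiology: v > 0 means the nostril is warming
(exhalation), v < 0 cooling (inhalation). The threshold

    theta[n] = alpha * MAD(v[n-L+1..n]) + eps

is scale-invariant, so the labeling adapts to amplitude and noise without
per-subject tuning. Transitions are gated on the persistence of the outgoing
state (dwell), and residual single-flicker segments shorter than the
consolidation window are merged away.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import signal as sps

from .errors import ConfigurationError, NotReadyError
from .signal_extraction import BreathSignal

__all__ = [
    "FilterSpec",
    "PhaseConfig",
    "PhaseTrace",
    "design_bandpass",
    "bandpass",
    "velocity_surrogate",
    "mad_threshold",
    "rolling_mad_threshold",
    "hysteresis_step",
    "run_hysteresis",
    "segments",
    "consolidate_flicker",
    "detect_phases",
]

INHALE, NEUTRAL, EXHALE = -1, 0, 1


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass design: 4th-order zero-phase Butterworth, 0.08-0.7 Hz.

    ``order`` is the overall filter order (pole count); a band-pass of order
    2N comes from an order-N low-pass prototype, so the default 4 uses N=2.
    Zero phase is obtained by forward-backward application, which preserves
    breath timing (no group delay) at the cost of the squared magnitude
    response.
    """

    low_hz: float = 0.08
    high_hz: float = 0.7
    order: int = 4
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.low_hz < self.high_hz:
            raise ConfigurationError(
                f"need 0 < low_hz < high_hz, got {self.low_hz}, {self.high_hz}"
            )
        if self.order < 2 or self.order % 2 != 0:
            raise ConfigurationError(
                f"band-pass order must be a positive even integer, got {self.order}"
            )


@dataclass(frozen=True)
class PhaseConfig:
    """Phase-detection tuning (defaults are the deployed operating point).

    velocity_window : samples in each moving average (W, default 3).
    mad_window : velocity history for the MAD threshold (L, default 21;
        sensible range 15-25).
    sensitivity : MAD multiplier alpha (default 0.6).
    epsilon : threshold floor in degC per window, guarding degeneracy when
        variability is minimal (default 1e-4).
    dwell_s : minimum dwell before a state may be left (default 0.15 s).
    consolidation_s : A->B->A segments shorter than this are merged (0.3 s).
    neutral_enabled : label |v| < theta as neutral/hold instead of keeping
        the previous phase (off by default; exhale-onset events only need
        entries into +1).
    """

    velocity_window: int = 3
    mad_window: int = 21
    sensitivity: float = 0.6
    epsilon: float = 1e-4
    dwell_s: float = 0.15
    consolidation_s: float = 0.3
    neutral_enabled: bool = False

    def __post_init__(self) -> None:
        if self.velocity_window < 2:
            raise ConfigurationError("velocity_window must be >= 2")
        if self.mad_window < 3:
            raise ConfigurationError("mad_window must be >= 3")
        if self.sensitivity <= 0 or self.epsilon <= 0:
            raise ConfigurationError("sensitivity and epsilon must be > 0")
        if self.dwell_s <= 0 or self.consolidation_s <= 0:
            raise ConfigurationError("dwell_s and consolidation_s must be > 0")


@dataclass
class PhaseTrace:
    """Per-sample phase labels plus the intermediate series that produced them."""

    labels: np.ndarray  # int8 in {-1, 0, +1}
    persistence: np.ndarray  # tau[n], samples in current state
    filtered: np.ndarray
    velocity: np.ndarray  # NaN where unavailable
    theta: np.ndarray  # NaN where unavailable
    f_cam: float
    change_points: np.ndarray = field(default=None)
    segment_states: np.ndarray = field(default=None)
    segment_lengths: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.change_points is None:
            cps, states, lengths = segments(self.labels)
            self.change_points = cps
            self.segment_states = states
            self.segment_lengths = lengths


def design_bandpass(f_cam: float, spec: FilterSpec = FilterSpec()) -> np.ndarray:
    """Second-order sections of the band-pass for sampling rate ``f_cam``."""
    if f_cam <= 2 * spec.high_hz:
        raise ConfigurationError(
            f"f_cam={f_cam} Hz must exceed twice the upper cutoff {spec.high_hz} Hz"
        )
    return sps.butter(
        spec.order // 2,
        [spec.low_hz, spec.high_hz],
        btype="bandpass",
        fs=f_cam,
        output="sos",
    )


def _min_samples(sos: np.ndarray) -> int:
    # sosfiltfilt default padlen; input must be strictly longer.
    ntaps = 2 * sos.shape[0] + 1
    return 3 * ntaps


def bandpass(
    x: np.ndarray, f_cam: float, spec: FilterSpec = FilterSpec()
) -> np.ndarray:
    """Zero-phase band-pass of a raw temperature sequence (DC removed)."""
    x = np.asarray(x, dtype=np.float64)
    sos = design_bandpass(f_cam, spec)
    if x.size <= _min_samples(sos):
        raise NotReadyError(
            f"need more than {_min_samples(sos)} samples to filter, got {x.size}"
        )
    if spec.zero_phase:
        return sps.sosfiltfilt(sos, x)
    return sps.sosfilt(sos, x)


def velocity_surrogate(filtered: np.ndarray, window: int = 3) -> np.ndarray:
    """Difference of two adjacent length-``window`` moving averages.

    v[n] = mean(x[n-W+1..n]) - mean(x[n-2W+1..n-W]); the first 2W-1 entries
    are unavailable and returned as NaN. On a ramp of slope m per sample,
    v = m*W everywhere valid.
    """
    x = np.asarray(filtered, dtype=np.float64)
    W = int(window)
    if x.size < 2 * W:
        raise NotReadyError(f"need at least {2 * W} samples, got {x.size}")
    csum = np.concatenate([[0.0], np.cumsum(x)])
    ma = (csum[W:] - csum[:-W]) / W  # ma[i] = mean(x[i..i+W-1])
    v = np.full(x.size, np.nan)
    # leading window ends at n  -> ma index n-W+1; lagging ends at n-W.
    v[2 * W - 1 :] = ma[W:] - ma[:-W]
    return v


def mad_threshold(
    v_window: np.ndarray, sensitivity: float = 0.6, epsilon: float = 1e-4
) -> float:
    """theta = alpha * median(|v - median(v)|) + eps; always >= eps."""
    v = np.asarray(v_window, dtype=np.float64)
    med = np.median(v)
    mad = np.median(np.abs(v - med))
    return float(sensitivity * mad + epsilon)


def rolling_mad_threshold(
    v: np.ndarray,
    mad_window: int = 21,
    sensitivity: float = 0.6,
    epsilon: float = 1e-4,
) -> np.ndarray:
    """Per-sample threshold from the last L available velocity values.

    Windows shorter than L (early in the sequence) use every velocity value
    available so far; entries where v itself is unavailable stay NaN.
    """
    v = np.asarray(v, dtype=np.float64)
    theta = np.full(v.size, np.nan)
    valid = np.flatnonzero(~np.isnan(v))
    for pos, n in enumerate(valid):
        lo = max(0, pos - mad_window + 1)
        theta[n] = mad_threshold(v[valid[lo : pos + 1]], sensitivity, epsilon)
    return theta


def hysteresis_step(
    prev_label: int,
    tau_prev: int,
    v: float,
    theta: float,
    n_min: int,
    neutral: bool = False,
) -> tuple[int, int]:
    """One dwell-gated hysteresis transition.

    The outgoing state must have persisted at least ``n_min`` samples before a
    crossing may switch the label; otherwise the previous label is kept (or
    neutral, when enabled and |v| < theta). The persistence counter resets on
    a change and increments otherwise.
    """
    if v >= theta and tau_prev >= n_min:
        label = EXHALE
    elif v <= -theta and tau_prev >= n_min:
        label = INHALE
    elif neutral and abs(v) < theta:
        label = NEUTRAL
    else:
        label = prev_label
    tau = 0 if label != prev_label else tau_prev + 1
    return label, tau


def run_hysteresis(
    v: np.ndarray,
    theta: np.ndarray,
    n_min: int,
    neutral: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Apply the hysteresis state machine over a full velocity sequence.

    The initial state is neutral with persistence already at ``n_min`` so the
    first genuine crossing can transition immediately; samples where v is
    unavailable keep the current state.
    """
    n = v.size
    labels = np.zeros(n, dtype=np.int8)
    persistence = np.zeros(n, dtype=np.int64)
    prev, tau = NEUTRAL, n_min
    for i in range(n):
        if np.isnan(v[i]) or np.isnan(theta[i]):
            label, tau = prev, tau + 1
        else:
            label, tau = hysteresis_step(prev, tau, v[i], theta[i], n_min, neutral)
        labels[i] = label
        persistence[i] = tau
        prev = label
    return labels, persistence


def segments(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Change-points n_i, per-segment states q_i and lengths L_i.

    ``change_points[0]`` is 0; each subsequent entry is the first index of a
    new segment.
    """
    labels = np.asarray(labels)
    if labels.size == 0:
        return np.array([], dtype=int), np.array([], dtype=int), np.array([], dtype=int)
    changes = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    cps = np.concatenate([[0], changes])
    states = labels[cps]
    lengths = np.diff(np.concatenate([cps, [labels.size]]))
    return cps, states.astype(int), lengths.astype(int)


def consolidate_flicker(labels: np.ndarray, n_c: int) -> np.ndarray:
    """Merge short A->B->A flickers into the flanking phase, to a fixed point.

    Every interior segment whose neighbors share a state different from its
    own and whose length is below ``n_c`` is relabeled to the flanking state;
    the scan repeats until no violation remains.
    """
    if n_c < 1:
        raise ConfigurationError(f"consolidation length must be >= 1, got {n_c}")
    out = np.asarray(labels).copy()
    while True:
        cps, states, lengths = segments(out)
        changed = False
        for i in range(1, len(states) - 1):
            if (
                states[i - 1] == states[i + 1]
                and states[i] != states[i - 1]
                and lengths[i] < n_c
            ):
                out[cps[i] : cps[i] + lengths[i]] = states[i - 1]
                changed = True
                break  # segment table is stale; rescan
        if not changed:
            return out


def detect_phases(
    signal: BreathSignal | np.ndarray,
    f_cam: Optional[float] = None,
    cfg: PhaseConfig = PhaseConfig(),
    spec: FilterSpec = FilterSpec(),
    min_span_s: float = 10.0,
) -> PhaseTrace:
    """Full phase-detection chain over a buffered temperature sequence.

    Accepts either a :class:`BreathSignal` (f_cam taken from it) or a plain
    array with ``f_cam`` given. Raises :class:`NotReadyError` until the buffer
    spans at least ``min_span_s`` seconds (default 10 s, enough for one breath
    at the slow end of the band) and the filter/velocity prerequisites.
    """
    if isinstance(signal, BreathSignal):
        values = signal.values
        f_cam = signal.f_cam
    else:
        values = np.asarray(signal, dtype=np.float64)
        if f_cam is None:
            raise ConfigurationError("f_cam required when passing a plain array")
    needed = max(
        int(np.ceil(min_span_s * f_cam)),
        2 * cfg.velocity_window,
        cfg.mad_window,
    )
    if values.size < needed:
        raise NotReadyError(
            f"buffer holds {values.size} samples; phase detection needs {needed}"
        )
    filtered = bandpass(values, f_cam, spec)
    v = velocity_surrogate(filtered, cfg.velocity_window)
    theta = rolling_mad_threshold(
        v, cfg.mad_window, cfg.sensitivity, cfg.epsilon
    )
    n_min = max(int(cfg.dwell_s * f_cam), 1)
    labels, persistence = run_hysteresis(v, theta, n_min, cfg.neutral_enabled)
    n_c = max(int(cfg.consolidation_s * f_cam), 1)
    labels = consolidate_flicker(labels, n_c)
    return PhaseTrace(
        labels=labels,
        persistence=persistence,
        filtered=filtered,
        velocity=v,
        theta=theta,
        f_cam=f_cam,
    )
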