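"""Respiratory-rate estimation from the consolidated phase trace.

Exhalation onsets — samples where the label enters +1 — are the breath
events. Consecutive events give inter-breath intervals (IBIs), each validated
against the physiological band 5-42 breaths/min (1.43 s <= IBI <= 12 s,
inclusive). Every validated interval yields an instantaneous rate 60/IBI,
which is stabilized by two lightweight causal smoothers in sequence:

    weighted update:  RRw_i = 0.6 * RR_i + 0.4 * RRw_{i-1}
    EMA:              RRf_i = 0.7 * RRw_i + 0.3 * RRf_{i-1}

Both are convex combinations, so the final rate can never leave the
[5, 42] BPM band once its inputs are validated. Invalid IBIs are dropped (not
clamped) and do not touch the smoothers; the displayed rate holds its last
value until the next valid interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import ConfigurationError

__all__ = [
    "RRConfig",
    "RREstimate",
    "exhale_onsets",
    "compute_ibis",
    "validate_ibi",
    "instantaneous_rr",
    "smooth_rr",
    "reference_rr",
    "estimate_rr",
    "rr_per_sample",
]


@dataclass(frozen=True)
class RRConfig:
    """IBI validation band and smoother coefficients.

    dt_min/dt_max bound plausible IBIs (defaults 60/42 s and 60/5 s, i.e. the
    5-42 BPM band, inclusive). w_new/w_prev weight the causal update
    (must sum to 1); ema_alpha is the EMA coefficient.
    """

    dt_min: float = 60.0 / 42.0
    dt_max: float = 60.0 / 5.0
    w_new: float = 0.6
    w_prev: float = 0.4
    ema_alpha: float = 0.7

    def __post_init__(self) -> None:
        if not 0 < self.dt_min < self.dt_max:
            raise ConfigurationError(
                f"need 0 < dt_min < dt_max, got {self.dt_min}, {self.dt_max}"
            )
        if abs(self.w_new + self.w_prev - 1.0) > 1e-12:
            raise ConfigurationError(
                f"w_new + w_prev must equal 1, got {self.w_new} + {self.w_prev}"
            )
        if not 0 < self.ema_alpha <= 1:
            raise ConfigurationError(
                f"ema_alpha must be in (0, 1], got {self.ema_alpha}"
            )


@dataclass
class RREstimate:
    """Events, intervals and the smoothed rate chain for one analysis run."""

    events: np.ndarray  # exhale-onset sample indices
    ibis: np.ndarray  # all IBIs, seconds (pre-validation)
    valid: np.ndarray  # bool mask over ibis
    rr_inst: np.ndarray  # BPM, validated intervals only
    rr_weighted: np.ndarray
    rr_final: np.ndarray
    f_cam: float

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    @property
    def n_invalid(self) -> int:
        return int((~self.valid).sum())

    @property
    def mean_rr(self) -> float:
        """Mean of the final smoothed rate; NaN before the first valid IBI."""
        if self.rr_final.size == 0:
            return float("nan")
        return float(np.mean(self.rr_final))


def exhale_onsets(labels: np.ndarray) -> np.ndarray:
    """Sample indices k >= 1 where the label enters +1 (s[k-1] != +1, s[k] = +1)."""
    labels = np.asarray(labels)
    if labels.size < 2:
        return np.array([], dtype=np.int64)
    onsets = np.flatnonzero((labels[1:] == 1) & (labels[:-1] != 1)) + 1
    return onsets.astype(np.int64)


def compute_ibis(events: np.ndarray, f_cam: float) -> np.ndarray:
    """Inter-breath intervals (seconds) between consecutive events."""
    if f_cam <= 0:
        raise ConfigurationError(f"f_cam must be > 0, got {f_cam}")
    events = np.asarray(events, dtype=np.float64)
    if events.size < 2:
        return np.array([], dtype=np.float64)
    return np.diff(events) / f_cam


def validate_ibi(dt: float | np.ndarray, cfg: RRConfig = RRConfig()):
    """True iff dt_min <= dt <= dt_max (bounds inclusive). Vectorizes."""
    dt = np.asarray(dt, dtype=np.float64)
    ok = (dt >= cfg.dt_min) & (dt <= cfg.dt_max)
    return bool(ok) if ok.ndim == 0 else ok


def instantaneous_rr(dt: float | np.ndarray):
    """Instantaneous respiratory rate 60/dt in BPM."""
    return 60.0 / np.asarray(dt, dtype=np.float64) if np.ndim(dt) else 60.0 / dt


def smooth_rr(
    rr_sequence: np.ndarray, cfg: RRConfig = RRConfig()
) -> tuple[np.ndarray, np.ndarray]:
    """Apply the weighted update then the EMA; both seeded with the first rate."""
    rr = np.asarray(rr_sequence, dtype=np.float64)
    if rr.size == 0:
        return np.array([]), np.array([])
    weighted = np.empty_like(rr)
    final = np.empty_like(rr)
    weighted[0] = rr[0]
    final[0] = rr[0]
    for i in range(1, rr.size):
        weighted[i] = cfg.w_new * rr[i] + cfg.w_prev * weighted[i - 1]
        final[i] = cfg.ema_alpha * weighted[i] + (1 - cfg.ema_alpha) * final[i - 1]
    return weighted, final


def reference_rr(n_breaths: int, duration_s: float) -> float:
    """Tally reference rate: breaths per observation window, scaled to BPM."""
    if duration_s <= 0:
        raise ConfigurationError(f"duration must be > 0, got {duration_s}")
    if n_breaths < 0:
        raise ConfigurationError(f"breath count must be >= 0, got {n_breaths}")
    return n_breaths / duration_s * 60.0


def estimate_rr(
    labels: np.ndarray, f_cam: float, cfg: RRConfig = RRConfig()
) -> RREstimate:
    """Run the event -> IBI -> validation -> smoothing chain over a phase trace.

    An onset that merely terminates the trace's initial neutral segment (the
    startup state, before any phase has been observed) anchors the first IBI
    but is itself a first classification, not a breath transition: the
    interval it would open spans an unknown fraction of a breath. Such an
    onset is dropped before interval computation.
    """
    labels = np.asarray(labels)
    events = exhale_onsets(labels)
    if (
        events.size
        and labels[0] == 0
        and np.all(labels[: events[0]] == 0)
    ):
        events = events[1:]
    ibis = compute_ibis(events, f_cam)
    valid = validate_ibi(ibis, cfg) if ibis.size else np.array([], dtype=bool)
    rr_inst = instantaneous_rr(ibis[valid]) if ibis.size else np.array([])
    rr_weighted, rr_final = smooth_rr(rr_inst, cfg)
    return RREstimate(
        events=events,
        ibis=ibis,
        valid=np.atleast_1d(valid),
        rr_inst=np.atleast_1d(rr_inst),
        rr_weighted=rr_weighted,
        rr_final=rr_final,
        f_cam=f_cam,
    )


def rr_per_sample(estimate: RREstimate, n_samples: int) -> np.ndarray:
    """Per-sample rate trace: the latest final rate held between events.

    NaN during warm-up, before the first validated interval exists. The i-th
    validated IBI is emitted at its closing event.
    """
    out = np.full(n_samples, np.nan)
    if estimate.rr_final.size == 0:
        return out
    closing_events = estimate.events[1:][estimate.valid]
    for value, k in zip(estimate.rr_final, closing_events):
        out[int(k):] = value
    return out
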