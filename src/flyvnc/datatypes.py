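"""Core in-memory containers shared across the pipeline.

Conventions: images and stacks are row-major float arrays with 0-based
(y, x) indexing; movie stacks are (T, Y, X). Axis semantics (e.g. which
direction is dorsal) live in acquisition metadata, never in code.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np


@dataclass
class FrameStack:
    """A single-channel movie: (T, Y, X) intensities in arbitrary units.

    Parameters
    ----------
    data : ndarray, shape (T, Y, X)
        Non-negative fluorescence intensities (or dF/F values, which may
        be negative).
    frame_rate : float
        Acquisition rate in Hz.
    channel : str
        One of ``"red"`` (anatomy marker, e.g. tdTomato), ``"green"``
        (calcium indicator, e.g. GCaMP6f) or ``"mono"``.
    """

    data: np.ndarray
    frame_rate: float = 16.0
    channel: str = "mono"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"expected (T, Y, X) stack, got shape {self.data.shape}")
        if self.data.shape[0] < 1:
            raise ValueError("stack must contain at least one frame")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("stack contains non-finite values")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def times(self) -> np.ndarray:
        """Frame acquisition times in seconds (frame i at i / frame_rate)."""
        return np.arange(self.n_frames) / self.frame_rate

    def copy_with(self, data: np.ndarray) -> "FrameStack":
        return FrameStack(data=data, frame_rate=self.frame_rate, channel=self.channel)


@dataclass
class MotionField:
    """Dense per-frame displacement relative to a reference frame.

    The field maps reference coordinates to frame coordinates (backward
    warping): ``corrected(p) = frame(p + (dy(p), dx(p)))``.
    """

    dy: np.ndarray
    dx: np.ndarray
    frame_index: int = 0

    def __post_init__(self) -> None:
        self.dy = np.asarray(self.dy, dtype=np.float64)
        self.dx = np.asarray(self.dx, dtype=np.float64)
        if self.dy.shape != self.dx.shape:
            raise ValueError("dy and dx must have the same shape")
        if not (np.all(np.isfinite(self.dy)) and np.all(np.isfinite(self.dx))):
            raise ValueError("motion field contains non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.dy.shape

    def magnitude(self) -> np.ndarray:
        return np.hypot(self.dy, self.dx)


@dataclass
class BaselineImage:
    """Per-pixel baseline fluorescence F0, floored at a small epsilon."""

    f0: np.ndarray
    epsilon: float

    def __post_init__(self) -> None:
        self.f0 = np.asarray(self.f0, dtype=np.float64)
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if np.any(self.f0 < self.epsilon):
            raise ValueError("baseline below epsilon floor")


@dataclass
class SampledTrace:
    """A uniformly sampled scalar or vector time series.

    ``values`` has shape (n,) or (n, k); sample i was taken at
    ``t0 + i / rate`` seconds.
    """

    values: np.ndarray
    rate: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.rate

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate


@dataclass
class GroundTruth:
    """Synthetic-data ground truth against which the pipeline is validated.

    Only the fields relevant to a given generator are populated.
    """

    true_motion_fields: Optional[list] = None
    roi_masks: Optional[np.ndarray] = None
    roi_regions: Optional[dict] = None          # roi label -> region name
    true_calcium_traces: Optional[dict] = None  # roi label -> SampledTrace
    illumination_gain: Optional[np.ndarray] = None
    wave_peak_times: Optional[dict] = None      # roi label -> seconds
    stationary_intervals: Optional[list] = None  # list of (start_s, end_s)
    true_velocities: Optional[np.ndarray] = None
    true_metrics: Optional[list] = None          # per-epoch LocomotionMetrics
    true_decay_rates: Optional[dict] = None      # roi label -> 1/day
    jitter: Optional[np.ndarray] = None          # per-day (dy, dx)
    extras: dict = field(default_factory=dict)
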