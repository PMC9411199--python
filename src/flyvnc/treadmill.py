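"""Spherical-treadmill sensor processing and synchronization.

A tethered fly walks on an air-supported 10 mm foam ball whose rotations
are read by two optic-flow sensors. The sensors view the ball's equator at
azimuths of +45 and -45 degrees from the fly's body axis; each reports
flow along two orthogonal axes (horizontal, vertical). Ball rotation about
the fly's pitch axis (forward walking), roll axis (sideways walking) and
yaw axis (turning) projects linearly onto the four sensor channels:

    s0_h = cos(45) * forward - sin(45) * sideways     (sensor at -45 deg)
    s0_v = turning
    s1_h = cos(45) * forward + sin(45) * sideways     (sensor at +45 deg)
    s1_v = turning

All rates are in ball rotations per second; a surface speed in mm/s is
rotations/s * pi * ball diameter. The same linear forward model is used by
the synthetic generator, so inversion can be validated by round trip.

Stationary periods (no ball movement) are classified with a two-part
rule: all three velocity components must be below 0.01 rotations/s
(0.31 mm/s surface speed for a 10 mm ball) at the sample, and at least
75% of samples within +-0.5 s must also be sub-threshold. The context
requirement discards short pauses between walking bouts.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .datatypes import SampledTrace

__all__ = [
    "SENSOR_MATRIX",
    "BallVelocities",
    "StationarityParams",
    "moving_average",
    "velocities_to_sensors",
    "sensors_to_velocities",
    "classify_stationary",
    "downsample_to_frames",
    "stationary_intervals_from_mask",
]

_C45 = np.cos(np.pi / 4)
_S45 = np.sin(np.pi / 4)

#: Linear map from (forward, sideways, turning) rotation rates to the four
#: sensor channels (sensor0_h, sensor0_v, sensor1_h, sensor1_v).
SENSOR_MATRIX = np.array(
    [
        [_C45, -_S45, 0.0],
        [0.0, 0.0, 1.0],
        [_C45, _S45, 0.0],
        [0.0, 0.0, 1.0],
    ]
)


@dataclass
class BallVelocities:
    """Body-frame ball rotation rates, all in rotations/s."""

    forward: np.ndarray
    sideways: np.ndarray
    turning: np.ndarray
    rate: float
    ball_diameter_mm: float = 10.0

    def __post_init__(self) -> None:
        n = len(self.forward)
        if len(self.sideways) != n or len(self.turning) != n:
            raise ValueError("velocity components must share length")

    def speed_mm_s(self, component: np.ndarray) -> np.ndarray:
        """Convert rotations/s to ball-surface speed in mm/s."""
        return component * np.pi * self.ball_diameter_mm

    def as_array(self) -> np.ndarray:
        return np.stack([self.forward, self.sideways, self.turning], axis=1)


@dataclass
class StationarityParams:
    speed_threshold: float = 0.01   # rotations/s (~0.31 mm/s on a 10 mm ball)
    context_halfwidth: float = 0.5  # s
    min_fraction: float = 0.75

    def __post_init__(self) -> None:
        if self.speed_threshold <= 0:
            raise ValueError("speed_threshold must be positive")
        if not (0 < self.min_fraction <= 1):
            raise ValueError("min_fraction must be in (0, 1]")


def moving_average(trace: SampledTrace, window: int = 80) -> SampledTrace:
    """Centered moving mean over ``window`` samples (~200 ms at 400 Hz).

    Edges are truncated and renormalized so the output has the same
    length; optic-flow sensor readings are inherently noisy and this is
    the first preprocessing step.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    values = trace.values
    n = values.shape[0]
    if window > n:
        raise ValueError(f"window {window} exceeds trace length {n}")
    if window == 1:
        return SampledTrace(values.copy(), trace.rate, trace.t0)
    kernel = np.ones(window) / window
    num = ndimage.convolve1d(values, kernel, axis=0, mode="constant", cval=0.0)
    norm = ndimage.convolve1d(np.ones(n), kernel, mode="constant", cval=0.0)
    shape = (n,) + (1,) * (values.ndim - 1)
    return SampledTrace(num / norm.reshape(shape), trace.rate, trace.t0)


def velocities_to_sensors(velocities: np.ndarray) -> np.ndarray:
    """Forward model: (n, 3) body-frame rates -> (n, 4) sensor readings."""
    velocities = np.atleast_2d(np.asarray(velocities, dtype=np.float64))
    if velocities.shape[1] != 3:
        raise ValueError("expected 3 velocity components")
    return velocities @ SENSOR_MATRIX.T


def sensors_to_velocities(
    traces: SampledTrace, ball_diameter_mm: float = 10.0
) -> BallVelocities:
    """Invert the sensor geometry to body-frame velocities.

    The 4 x 3 sensor matrix has full column rank; the inverse is the
    least-squares pseudo-inverse, which averages the two redundant
    vertical (turning) channels.
    """
    values = traces.values
    if values.ndim != 2 or values.shape[1] != 4:
        raise ValueError("expected 4 sensor channels (2 sensors x 2 axes)")
    pinv = np.linalg.pinv(SENSOR_MATRIX)
    vel = values @ pinv.T
    return BallVelocities(
        forward=vel[:, 0],
        sideways=vel[:, 1],
        turning=vel[:, 2],
        rate=traces.rate,
        ball_diameter_mm=ball_diameter_mm,
    )


def classify_stationary(
    vel: BallVelocities, params: StationarityParams | None = None
) -> np.ndarray:
    """Boolean per-sample mask of stationary (ball not moving) periods.

    Sample s is stationary iff all three |components| are below the
    threshold at s AND at least ``min_fraction`` of the samples within
    ``context_halfwidth`` seconds of s are sub-threshold. Edge windows
    use only the available samples.
    """
    params = params or StationarityParams()
    arr = np.abs(vel.as_array())
    below = np.all(arr < params.speed_threshold, axis=1)
    half = int(round(params.context_halfwidth * vel.rate))
    if half == 0:
        return below
    window = 2 * half + 1
    kernel = np.ones(window)
    counts = ndimage.convolve1d(
        below.astype(np.float64), kernel, mode="constant", cval=0.0
    )
    avail = ndimage.convolve1d(
        np.ones(below.shape[0]), kernel, mode="constant", cval=0.0
    )
    frac = counts / avail
    return below & (frac >= params.min_fraction)


def stationary_intervals_from_mask(mask: np.ndarray, rate: float) -> list[tuple[float, float]]:
    """Convert a boolean sample mask into (start_s, end_s) intervals."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return []
    padded = np.diff(np.concatenate([[0], mask.astype(int), [0]]))
    starts = np.flatnonzero(padded == 1)
    ends = np.flatnonzero(padded == -1)
    return [(s / rate, e / rate) for s, e in zip(starts, ends)]


def downsample_to_frames(
    trace: SampledTrace, frame_rate: float, n_frames: int
) -> np.ndarray:
    """Average samples within each two-photon frame interval.

    Frame i aggregates samples with time in [i/frame_rate,
    (i+1)/frame_rate). Boolean traces aggregate by majority vote. A frame
    interval containing no samples yields NaN with a warning (only
    possible if the sample rate is below the frame rate).
    """
    import warnings

    values = trace.values
    is_bool = values.dtype == bool or np.array_equal(values, values.astype(bool))
    t = trace.times - trace.t0
    frame_idx = np.floor(t * frame_rate).astype(int)
    valid = (frame_idx >= 0) & (frame_idx < n_frames)

    out_shape = (n_frames,) + values.shape[1:]
    sums = np.zeros(out_shape)
    counts = np.zeros(n_frames)
    np.add.at(counts, frame_idx[valid], 1)
    if values.ndim == 1:
        np.add.at(sums, frame_idx[valid], values[valid])
    else:
        for k in range(values.shape[1]):
            np.add.at(sums[:, k], frame_idx[valid], values[valid, k])

    empty = counts == 0
    if empty.any():
        warnings.warn(f"{int(empty.sum())} frame intervals contain no samples")
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = counts if values.ndim == 1 else counts[:, None]
        means = sums / denom
    means[empty] = np.nan
    if is_bool:
        # majority vote, encoded 0/1 with NaN marking empty frames
        out = (means > 0.5).astype(np.float64)
        out[empty] = np.nan
        return out
    return means
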