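"""Optogenetic backward-walking metrics from arena trajectories.

Flies expressing CsChrimson in Moonwalker Descending Neurons walk
backward during optogenetic stimulation. Each recording session consists
of 30 s of spontaneous behavior followed by three 3 s stimulation epochs
separated by 10 s inter-stimulus intervals (59 s total). Centroid
trajectories are tracked at 80 fps; three per-epoch metrics quantify the
backward-walking response:

- response slope: acceleration from stimulation onset to the epoch's
  minimum velocity (mm/s^2, negative for backward responses);
- backward distance: left Riemann sum of the velocity over epoch frames
  where the velocity is negative (mm, <= 0);
- maximum negative velocity: the minimum velocity reached in the epoch.

Epochs with more than 0.3 s of wall contact, or any dorsally-flipped
frame, are excluded.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .datatypes import SampledTrace

__all__ = [
    "Trajectory",
    "StimEpoch",
    "LocomotionMetrics",
    "translational_velocity",
    "exclude_epochs",
    "response_slope",
    "backward_distance",
    "max_negative_velocity",
    "session_schedule",
]


@dataclass
class Trajectory:
    """Arena centroid/heading track at the camera frame rate."""

    centroid: np.ndarray          # (n, 2) mm, columns (x, y)
    heading: np.ndarray           # (n,) radians or (n, 2) unit vectors
    rate: float = 80.0
    wall_contact: np.ndarray | None = None  # (n,) bool
    flipped: np.ndarray | None = None       # (n,) bool

    def __post_init__(self) -> None:
        self.centroid = np.asarray(self.centroid, dtype=np.float64)
        if self.centroid.ndim != 2 or self.centroid.shape[1] != 2:
            raise ValueError("centroid must be (n, 2)")
        n = self.centroid.shape[0]
        self.heading = np.asarray(self.heading, dtype=np.float64)
        if self.heading.ndim == 1:
            self.heading = np.stack(
                [np.cos(self.heading), np.sin(self.heading)], axis=1
            )
        if self.heading.shape != (n, 2):
            raise ValueError("heading must be (n,) angles or (n, 2) vectors")
        if self.wall_contact is None:
            self.wall_contact = np.zeros(n, dtype=bool)
        if self.flipped is None:
            self.flipped = np.zeros(n, dtype=bool)

    @property
    def n_frames(self) -> int:
        return self.centroid.shape[0]


@dataclass
class StimEpoch:
    onset: float            # s
    duration: float = 3.0   # s
    index: int = 0

    def __post_init__(self) -> None:
        if self.onset < 0 or self.duration <= 0:
            raise ValueError("invalid stimulation epoch")

    def frame_slice(self, rate: float) -> slice:
        start = int(round(self.onset * rate))
        stop = int(round((self.onset + self.duration) * rate))
        return slice(start, stop)


@dataclass
class LocomotionMetrics:
    response_slope: float        # mm/s^2
    backward_distance: float     # mm, <= 0
    max_negative_velocity: float  # mm/s
    epoch_index: int = 0
    excluded: bool = False
    exclusion_reason: str = ""


def translational_velocity(
    traj: Trajectory, savgol_window: int = 9, order: int = 2
) -> SampledTrace:
    """Signed translational velocity (mm/s) from centroid positions.

    Speed is the magnitude of the Savitzky-Golay first derivative
    (second-order polynomial window) of the centroid; the sign is
    negative when the displacement opposes the heading direction. The
    order-2 filter differentiates quadratic trajectories exactly on
    interior frames.
    """
    if savgol_window % 2 == 0 or savgol_window <= order:
        raise ValueError("savgol_window must be odd and exceed the polynomial order")
    if traj.n_frames < savgol_window:
        raise ValueError("trajectory shorter than filter window")
    dt = 1.0 / traj.rate
    vx = savgol_filter(traj.centroid[:, 0], savgol_window, order, deriv=1, delta=dt)
    vy = savgol_filter(traj.centroid[:, 1], savgol_window, order, deriv=1, delta=dt)
    speed = np.hypot(vx, vy)
    along = vx * traj.heading[:, 0] + vy * traj.heading[:, 1]
    signed = np.where(along < 0, -speed, speed)
    return SampledTrace(signed, traj.rate)


def exclude_epochs(
    traj: Trajectory, epochs: list[StimEpoch]
) -> list[tuple[StimEpoch, bool, str]]:
    """Apply the per-epoch exclusion rules.

    An epoch is excluded iff cumulative wall contact during it exceeds
    0.3 s (strictly more), or the fly is dorsally flipped on any frame.
    Returns (epoch, excluded, reason) triples.
    """
    results = []
    for epoch in epochs:
        sl = epoch.frame_slice(traj.rate)
        if sl.stop > traj.n_frames:
            raise ValueError(f"epoch {epoch.index} extends past trajectory end")
        contact_s = traj.wall_contact[sl].sum() / traj.rate
        flipped = bool(traj.flipped[sl].any())
        if contact_s > 0.3:
            results.append((epoch, True, f"wall contact {contact_s:.2f} s > 0.3 s"))
        elif flipped:
            results.append((epoch, True, "dorsally flipped during stimulation"))
        else:
            results.append((epoch, False, ""))
    return results


def _epoch_values(vel: SampledTrace, epoch: StimEpoch) -> np.ndarray:
    sl = epoch.frame_slice(vel.rate)
    if sl.stop > vel.n_samples or sl.start >= sl.stop:
        raise ValueError("epoch outside velocity trace")
    return vel.values[sl]


def response_slope(vel: SampledTrace, epoch: StimEpoch) -> float:
    """Acceleration (mm/s^2) from stimulation onset to the epoch's
    minimum velocity; 0 with a warning if the minimum is at onset."""
    v = _epoch_values(vel, epoch)
    i_min = int(np.argmin(v))
    if i_min == 0:
        warnings.warn("velocity minimum at stimulation onset; slope undefined, 0")
        return 0.0
    return float((v[i_min] - v[0]) / (i_min / vel.rate))


def backward_distance(vel: SampledTrace, epoch: StimEpoch) -> float:
    """Left Riemann sum of the velocity over epoch frames with v < 0 (mm)."""
    v = _epoch_values(vel, epoch)
    dt = 1.0 / vel.rate
    return float(v[v < 0].sum() * dt)


def max_negative_velocity(vel: SampledTrace, epoch: StimEpoch) -> float:
    """Minimum velocity reached during the epoch (mm/s)."""
    return float(_epoch_values(vel, epoch).min())


def compute_epoch_metrics(
    vel: SampledTrace,
    traj: Trajectory,
    epochs: list[StimEpoch],
) -> list[LocomotionMetrics]:
    """All three backward-walking metrics per epoch, with exclusions."""
    out = []
    for epoch, excluded, reason in exclude_epochs(traj, epochs):
        out.append(
            LocomotionMetrics(
                response_slope=response_slope(vel, epoch),
                backward_distance=backward_distance(vel, epoch),
                max_negative_velocity=max_negative_velocity(vel, epoch),
                epoch_index=epoch.index,
                excluded=excluded,
                exclusion_reason=reason,
            )
        )
    return out


def session_schedule(
    spontaneous_duration: float = 30.0,
    n_stims: int = 3,
    stim_duration: float = 3.0,
    inter_stim_interval: float = 10.0,
) -> tuple[list[StimEpoch], float]:
    """Stimulation epochs and total session length.

    Defaults give onsets at 30, 43 and 56 s and a 59 s session:
    30 + 3*3 + 2*10 = 59.
    """
    if min(spontaneous_duration, stim_duration, inter_stim_interval) <= 0:
        raise ValueError("durations must be positive")
    epochs = [
        StimEpoch(
            onset=spontaneous_duration + i * (stim_duration + inter_stim_interval),
            duration=stim_duration,
            index=i,
        )
        for i in range(n_stims)
    ]
    total = (
        spontaneous_duration
        + n_stims * stim_duration
        + max(n_stims - 1, 0) * inter_stim_interval
    )
    return epochs, total
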