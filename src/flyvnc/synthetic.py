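"""Synthetic-data generators with ground truth for every pipeline stage.

Each generator emulates one input modality of the long-term VNC imaging
experiments and returns the exact ground truth needed to validate the
corresponding analysis stage:

- two-channel connective movies with known rigid + smooth non-rigid
  motion, a left-right illumination gradient, elliptical axon
  cross-sections grouped into four connective regions, locomotion-locked
  calcium fluctuations and optional large traveling waves with a known
  region order;
- two-sensor spherical-treadmill traces produced by the same linear
  forward model the analysis inverts, with labeled stationary segments;
- arena centroid trajectories following the optogenetic stimulation
  protocol (30 s spontaneous, three 3 s stimulations, 10 s intervals),
  with analytic per-epoch locomotion metrics;
- multi-day image series separating photobleaching from amputation-
  induced decay, with known per-day jitter and decay rates.

All generators are deterministic given (spec, seed).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .arena import StimEpoch, Trajectory
from .datatypes import FrameStack, GroundTruth, MotionField, SampledTrace
from .treadmill import velocities_to_sensors

__all__ = [
    "WaveSpec",
    "ConnectiveMovieSpec",
    "SensorTraceSpec",
    "ArenaTrajectorySpec",
    "DegradationSeriesSpec",
    "generate_connective_movie",
    "generate_sensor_traces",
    "generate_arena_trajectory",
    "generate_degradation_series",
]

REGIONS = ("dorsomedial", "dorsolateral", "ventral", "giant_fiber")


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass
class WaveSpec:
    """A large traveling activity wave sweeping the connective regions in
    a fixed order (dorsomedial, then dorsolateral, then ventral, with the
    giant fibers last by default)."""

    onset_time: float = 3.0            # s, peak time of the first region
    region_order: tuple[str, ...] = REGIONS
    inter_region_lag: float = 0.5      # s between successive region peaks
    amplitude: float = 4.0             # multiple of locomotor fluctuations
    duration: float = 2.0              # s, wave width (4 sigma)

    def __post_init__(self) -> None:
        if self.inter_region_lag < 0:
            raise ValueError("inter_region_lag must be >= 0")
        if self.amplitude <= 0 or self.duration <= 0:
            raise ValueError("amplitude and duration must be positive")
        unknown = set(self.region_order) - set(REGIONS)
        if unknown:
            raise ValueError(f"unknown regions: {unknown}")


@dataclass
class ConnectiveMovieSpec:
    """Two-channel coronal connective movie specification.

    Default frame size is reduced (128 x 192) to keep tests fast; the
    full acquisition size of 480 x 736 is supported.
    """

    n_frames: int = 64
    frame_rate: float = 16.0
    height: int = 128
    width: int = 192
    n_axons: int = 12
    motion_amplitude: float = 3.0      # px, rigid translation
    nonrigid_amplitude: float = 1.0    # px, smooth deformation
    illumination_slope: float = 0.0    # fractional gain change / px in x
    noise_sd: float = 2.0              # a.u.
    fluctuation_amplitude: float = 0.25  # relative locomotor dF amplitude
    wave: Optional[WaveSpec] = None
    seed: int = 0
    layout_seed: Optional[int] = None  # fix the axon layout across trials

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.height < 32 or self.width < 32:
            raise ValueError("frame size too small for axon layout")
        if self.noise_sd < 0 or self.motion_amplitude < 0 or self.nonrigid_amplitude < 0:
            raise ValueError("amplitudes and noise must be non-negative")
        if self.n_axons < 4:
            raise ValueError("need at least one axon per region")


@dataclass
class SensorTraceSpec:
    """Spherical-treadmill sensor recording specification.

    ``segments`` is a list of (start_s, end_s, forward, sideways, turn)
    with rotation rates in rotations/s; time outside all segments has
    zero true rotation.
    """

    duration: float = 10.0
    rate: float = 400.0
    ball_diameter: float = 10.0        # mm
    segments: Sequence[tuple] = ()
    sensor_noise_sd: float = 0.0       # rotations/s
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.rate <= 0:
            raise ValueError("duration and rate must be positive")
        spans = sorted((s[0], s[1]) for s in self.segments)
        last_end = 0.0
        for start, end in spans:
            if start < 0 or end > self.duration or end <= start:
                raise ValueError("segments must lie inside [0, duration]")
            if start < last_end:
                raise ValueError("segments must not overlap")
            last_end = end


@dataclass
class ArenaTrajectorySpec:
    """Arena session: spontaneous walking, then optogenetic backward-
    walking epochs following the stimulation protocol."""

    camera_rate: float = 80.0
    spontaneous_duration: float = 30.0
    n_stims: int = 3
    stim_duration: float = 3.0
    inter_stim_interval: float = 10.0
    baseline_speed: float = 10.0       # mm/s forward
    backward_peak_speed: float = 15.0  # mm/s
    response_slope: float = 25.0       # mm/s^2 (magnitude of the ramp)
    recovery_fraction: float = 0.4     # of peak speed recovered within the stim
    relax_time: float = 2.0            # s to return to baseline after stim
    noise_sd: float = 0.0              # mm, centroid jitter
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.camera_rate, self.spontaneous_duration, self.stim_duration) <= 0:
            raise ValueError("rates and durations must be positive")
        if self.n_stims < 0:
            raise ValueError("n_stims must be >= 0")
        if self.n_stims > 1 and self.inter_stim_interval <= 0:
            raise ValueError("inter_stim_interval must be positive")
        if self.response_slope <= 0 or self.backward_peak_speed <= 0:
            raise ValueError("response parameters must be positive")

    @property
    def total_duration(self) -> float:
        return (
            self.spontaneous_duration
            + self.n_stims * self.stim_duration
            + max(self.n_stims - 1, 0) * self.inter_stim_interval
        )


@dataclass
class DegradationSeriesSpec:
    """Daily projection series for intact vs. amputated flies."""

    n_days: int = 15
    height: int = 96
    width: int = 96
    n_rois: int = 3
    amputated_rois: tuple[int, ...] = (1,)  # ROI labels decaying after amputation
    bleach_rate: float = 0.02          # 1/day, all ROIs, both groups
    amputation_decay_rate: float = 0.25  # 1/day, designated ROIs from day 2
    jitter: float = 2.0                # px, day-to-day translation
    noise_sd: float = 0.0              # a.u.
    n_flies_per_group: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_days < 2:
            raise ValueError("n_days must be >= 2")
        if self.bleach_rate < 0 or self.amputation_decay_rate < 0:
            raise ValueError("rates must be >= 0")


# ---------------------------------------------------------------------------
# Connective movie
# ---------------------------------------------------------------------------

def _axon_layout(spec: ConnectiveMovieSpec, rng: np.random.Generator):
    """Place elliptical axon cross-sections into four connective regions.

    Regions occupy fixed bands of the frame: giant fibers at the dorsal
    midline, dorsomedial and dorsolateral bands below, ventral at the
    bottom. Returns (centers, sigmas, amplitudes, region names, labels).
    """
    h, w = spec.height, spec.width
    bands = {
        "giant_fiber": (0.16 * h, (0.40 * w, 0.60 * w)),
        "dorsomedial": (0.32 * h, (0.30 * w, 0.70 * w)),
        "dorsolateral": (0.50 * h, (0.15 * w, 0.85 * w)),
        "ventral": (0.72 * h, (0.25 * w, 0.75 * w)),
    }
    per_region = [REGIONS[i % 4] for i in range(spec.n_axons)]
    counts = {r: per_region.count(r) for r in REGIONS}
    centers, sigmas, amps, regions = [], [], [], []
    for region in REGIONS:
        n = counts[region]
        if n == 0:
            continue
        y_band, (x_lo, x_hi) = bands[region]
        xs = np.linspace(x_lo, x_hi, n + 2)[1:-1]
        for x in xs:
            cy = y_band + rng.uniform(-1.5, 1.5)
            cx = x + rng.uniform(-1.5, 1.5)
            sy = rng.uniform(2.0, 3.0)
            sx = rng.uniform(2.5, 4.0)
            centers.append((cy, cx))
            sigmas.append((sy, sx))
            amps.append(rng.uniform(80.0, 150.0))
            regions.append(region)
    labels = list(range(1, len(centers) + 1))
    return centers, sigmas, amps, regions, labels


def _axon_blobs(shape, centers, sigmas) -> np.ndarray:
    """Unit-amplitude 2-D Gaussians truncated to ellipses (2.5 sigma),
    one image per axon, stacked as (n_axons, Y, X)."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    blobs = np.zeros((len(centers), h, w))
    for i, ((cy, cx), (sy, sx)) in enumerate(zip(centers, sigmas)):
        r2 = ((yy - cy) / sy) ** 2 + ((xx - cx) / sx) ** 2
        blob = np.exp(-0.5 * r2)
        blob[r2 > 2.5**2] = 0.0
        blobs[i] = blob
    return blobs


def _roi_masks(shape, centers, sigmas, labels) -> np.ndarray:
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    mask = np.zeros(shape, dtype=np.int32)
    for (cy, cx), (sy, sx), label in zip(centers, sigmas, labels):
        r2 = ((yy - cy) / sy) ** 2 + ((xx - cx) / sx) ** 2
        mask[r2 <= 2.0**2] = label
    return mask


def _smooth_random_trace(
    rng: np.random.Generator, n: int, amplitude: float, sigma: float = 5.0
) -> np.ndarray:
    """Smooth zero-at-origin random trace with max |value| = amplitude."""
    if amplitude == 0 or n < 2:
        return np.zeros(n)
    raw = ndimage.gaussian_filter1d(rng.standard_normal(n + 20), sigma)[10:-10]
    raw -= raw[0]
    peak = np.abs(raw).max()
    return raw * (amplitude / peak) if peak > 0 else raw


def _nonrigid_bases(h: int, w: int) -> list[np.ndarray]:
    yy, xx = np.mgrid[0:h, 0:w]
    sy, sx = yy * np.pi / (h - 1), xx * np.pi / (w - 1)
    return [
        np.sin(sy) * np.sin(sx),
        np.sin(2 * sy) * np.sin(sx),
        np.sin(sy) * np.sin(2 * sx),
    ]


def generate_connective_movie(
    spec: ConnectiveMovieSpec,
) -> tuple[FrameStack, FrameStack, GroundTruth]:
    """Generate a two-channel connective movie with full ground truth.

    The red (anatomy) channel is a static template of elliptical axons
    deformed per frame by the true motion field and multiplied by the
    illumination gain; the green (calcium) channel shares the geometry
    and motion but scales each axon by its calcium trace. Motion fields
    follow the backward-warp convention used by the correction stage:
    warping frame t by ``truth.true_motion_fields[t]`` recovers the
    reference geometry. Frame 0 carries zero motion.
    """
    rng = np.random.default_rng(spec.seed)
    layout_rng = (
        rng if spec.layout_seed is None else np.random.default_rng(spec.layout_seed)
    )
    h, w, T = spec.height, spec.width, spec.n_frames
    centers, sigmas, amps, regions, labels = _axon_layout(spec, layout_rng)

    blobs = _axon_blobs((h, w), centers, sigmas)
    red_template = 10.0 + np.tensordot(np.asarray(amps), blobs, axes=1)
    green_amps = layout_rng.uniform(60.0, 120.0, size=len(centers))
    roi_masks = _roi_masks((h, w), centers, sigmas, labels)

    # calcium traces: baseline 1 + locomotor fluctuations + optional wave
    times = np.arange(T) / spec.frame_rate
    traces = {}
    wave_peak_times: dict[int, float] = {}
    region_rank = (
        {r: i for i, r in enumerate(spec.wave.region_order)} if spec.wave else {}
    )
    for label, region in zip(labels, regions):
        tr = 1.0 + _smooth_random_trace(rng, T, spec.fluctuation_amplitude)
        if spec.wave is not None and region in region_rank:
            t_peak = spec.wave.onset_time + region_rank[region] * spec.wave.inter_region_lag
            sigma_t = spec.wave.duration / 4.0
            bump_height = spec.wave.amplitude * max(spec.fluctuation_amplitude, 0.25)
            tr = tr + bump_height * np.exp(-0.5 * ((times - t_peak) / sigma_t) ** 2)
            wave_peak_times[label] = t_peak
        traces[label] = SampledTrace(tr, spec.frame_rate)

    green_blobs = green_amps[:, None, None] * blobs
    trace_matrix = np.stack([traces[label].values for label in labels])  # (n, T)

    # motion: rigid translation + low-order smooth non-rigid field
    rig_dy = _smooth_random_trace(rng, T, spec.motion_amplitude)
    rig_dx = _smooth_random_trace(rng, T, spec.motion_amplitude)
    bases = _nonrigid_bases(h, w)
    coeffs = [
        (
            _smooth_random_trace(rng, T, spec.nonrigid_amplitude / 3.0),
            _smooth_random_trace(rng, T, spec.nonrigid_amplitude / 3.0),
        )
        for _ in bases
    ]

    gain_x = 1.0 + spec.illumination_slope * (np.arange(w) - w / 2.0)
    if np.any(gain_x <= 0):
        raise ValueError("illumination_slope produces non-positive gain")
    gain = np.broadcast_to(gain_x, (h, w)).copy()

    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    fields: list[MotionField] = []
    red = np.empty((T, h, w))
    green = np.empty((T, h, w))
    for t in range(T):
        dy = np.full((h, w), rig_dy[t])
        dx = np.full((h, w), rig_dx[t])
        for (cy, cx), basis in zip(coeffs, bases):
            dy += cy[t] * basis
            dx += cx[t] * basis
        fields.append(MotionField(dy=dy, dx=dx, frame_index=t))

        green_template = 5.0 + np.tensordot(trace_matrix[:, t], green_blobs, axes=1)
        if np.abs(dy).max() == 0 and np.abs(dx).max() == 0:
            red_t, green_t = red_template, green_template
        else:
            # forward-deform the template so that backward-warping the
            # frame by the true field recovers the template
            coords = np.stack([yy - dy, xx - dx])
            red_t = ndimage.map_coordinates(red_template, coords, order=1, mode="nearest")
            green_t = ndimage.map_coordinates(green_template, coords, order=1, mode="nearest")
        red[t] = red_t * gain
        green[t] = green_t * gain
    if spec.noise_sd > 0:
        red = np.clip(red + rng.normal(0, spec.noise_sd, red.shape), 0, None)
        green = np.clip(green + rng.normal(0, spec.noise_sd, green.shape), 0, None)

    truth = GroundTruth(
        true_motion_fields=fields,
        roi_masks=roi_masks,
        roi_regions={label: region for label, region in zip(labels, regions)},
        true_calcium_traces=traces,
        illumination_gain=gain,
        wave_peak_times=wave_peak_times or None,
    )
    return (
        FrameStack(red, spec.frame_rate, "red"),
        FrameStack(green, spec.frame_rate, "green"),
        truth,
    )


# ---------------------------------------------------------------------------
# Sensor traces
# ---------------------------------------------------------------------------

def generate_sensor_traces(
    spec: SensorTraceSpec,
) -> tuple[SampledTrace, GroundTruth]:
    """Raw two-sensor treadmill readings via the documented forward model.

    True body-frame velocities are piecewise constant per segment (zero
    outside all segments), pushed through the sensor geometry matrix and
    optionally corrupted with Gaussian noise. Stationary intervals in the
    truth are the maximal spans where all true rotation rates are zero.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.rate))
    t = np.arange(n) / spec.rate
    vel = np.zeros((n, 3))
    for seg in spec.segments:
        start, end, fwd, side, turn = seg
        sel = (t >= start) & (t < end)
        vel[sel] = (fwd, side, turn)

    readings = velocities_to_sensors(vel)
    if spec.sensor_noise_sd > 0:
        readings = readings + rng.normal(0, spec.sensor_noise_sd, readings.shape)

    moving = np.any(vel != 0, axis=1)
    intervals = []
    start_idx = None
    for i in range(n):
        if not moving[i] and start_idx is None:
            start_idx = i
        elif moving[i] and start_idx is not None:
            intervals.append((start_idx / spec.rate, i / spec.rate))
            start_idx = None
    if start_idx is not None:
        intervals.append((start_idx / spec.rate, n / spec.rate))

    truth = GroundTruth(true_velocities=vel, stationary_intervals=intervals)
    return SampledTrace(readings, spec.rate), truth


# ---------------------------------------------------------------------------
# Arena trajectory
# ---------------------------------------------------------------------------

def _arena_velocity_profile(spec: ArenaTrajectorySpec) -> np.ndarray:
    """Noiseless signed velocity per frame for the stimulation protocol."""
    n = int(round(spec.total_duration * spec.camera_rate))
    t = np.arange(n) / spec.camera_rate
    v = np.full(n, spec.baseline_speed)
    ramp_time = (spec.baseline_speed + spec.backward_peak_speed) / spec.response_slope
    if spec.n_stims > 0 and ramp_time >= spec.stim_duration:
        raise ValueError("response ramp longer than the stimulation epoch")
    for i in range(spec.n_stims):
        onset = spec.spontaneous_duration + i * (
            spec.stim_duration + spec.inter_stim_interval
        )
        end = onset + spec.stim_duration
        in_stim = (t >= onset) & (t < end)
        tau = t[in_stim] - onset
        ramp = spec.baseline_speed - spec.response_slope * tau
        # after the backward peak, speed partially recovers during the
        # remainder of the stimulation (as in real backward-walking bouts),
        # giving the profile a unique minimum at the end of the ramp
        t_peak = (spec.baseline_speed + spec.backward_peak_speed) / spec.response_slope
        recovery_span = max(spec.stim_duration - t_peak, 1e-9)
        recovery = -spec.backward_peak_speed + (
            spec.recovery_fraction * spec.backward_peak_speed
        ) * (tau - t_peak) / recovery_span
        v[in_stim] = np.where(tau < t_peak, ramp, recovery)
        v_end = -spec.backward_peak_speed * (1 - spec.recovery_fraction)
        # linear relaxation back to baseline during the inter-stimulus gap
        relax = min(spec.relax_time, spec.inter_stim_interval)
        in_relax = (t >= end) & (t < end + relax)
        frac = (t[in_relax] - end) / relax
        v[in_relax] = v_end + frac * (spec.baseline_speed - v_end)
    return v


def generate_arena_trajectory(
    spec: ArenaTrajectorySpec,
) -> tuple[Trajectory, GroundTruth]:
    """Arena centroid trajectory with analytic per-epoch metrics.

    The fly walks forward at baseline speed, ramps to backward walking at
    each stimulation onset, and relaxes back during the inter-stimulus
    interval. Heading is constant, so the signed velocity equals the
    generator profile. Truth metrics apply the documented metric
    definitions (onset-to-minimum slope, negative-only left Riemann sum,
    epoch minimum) to the noiseless velocity samples.
    """
    from .arena import LocomotionMetrics

    rng = np.random.default_rng(spec.seed)
    v = _arena_velocity_profile(spec)
    n = v.shape[0]
    dt = 1.0 / spec.camera_rate
    heading = np.zeros(n)  # constant heading along +x
    # left Riemann integration of the velocity, matching the analysis
    x = np.concatenate([[0.0], np.cumsum(v[:-1]) * dt])
    centroid = np.stack([x, np.zeros(n)], axis=1)
    if spec.noise_sd > 0:
        centroid = centroid + rng.normal(0, spec.noise_sd, centroid.shape)

    epochs = [
        StimEpoch(
            onset=spec.spontaneous_duration
            + i * (spec.stim_duration + spec.inter_stim_interval),
            duration=spec.stim_duration,
            index=i,
        )
        for i in range(spec.n_stims)
    ]
    metrics = []
    for epoch in epochs:
        sl = epoch.frame_slice(spec.camera_rate)
        ve = v[sl]
        i_min = int(np.argmin(ve))
        slope = (ve[i_min] - ve[0]) / (i_min * dt) if i_min > 0 else 0.0
        dist = float(ve[ve < 0].sum() * dt)
        metrics.append(
            LocomotionMetrics(
                response_slope=float(slope),
                backward_distance=dist,
                max_negative_velocity=float(ve.min()),
                epoch_index=epoch.index,
            )
        )
    traj = Trajectory(centroid=centroid, heading=heading, rate=spec.camera_rate)
    truth = GroundTruth(
        true_velocities=v, true_metrics=metrics, extras={"epochs": epochs}
    )
    return traj, truth


# ---------------------------------------------------------------------------
# Degradation series
# ---------------------------------------------------------------------------

def generate_degradation_series(
    spec: DegradationSeriesSpec,
) -> tuple[list, GroundTruth]:
    """Daily projection series for intact and amputated fly groups.

    All ROIs photobleach as exp(-bleach_rate * (day - 1)). In amputated
    flies the designated ROIs additionally decay as
    exp(-amputation_decay_rate * (day - 2)) from day 2 onward (the leg is
    amputated at 2 dpi, so day 2 itself is unaffected). Each day's image
    is translated by a recorded random jitter.

    Returns (list of DailySeries, truth); truth.true_decay_rates maps
    (group, roi_id) to the total decay rate, truth.jitter holds per-fly
    (n_days, 2) offsets in ``extras``.
    """
    from .degradation import DailySeries

    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    yy, xx = np.mgrid[0:h, 0:w]

    # ROI blobs on a fixed grid
    n = spec.n_rois
    cys = np.linspace(0.25 * h, 0.75 * h, n)
    cxs = np.linspace(0.3 * w, 0.7 * w, n)
    # blob support (4 r) must stay clear of neighbouring ROI masks (3 r)
    radius = min(h, w) / (8 * max(n, 2))
    rois = np.zeros((h, w), dtype=np.int32)
    blobs = []
    for i in range(n):
        r2 = (yy - cys[i]) ** 2 + (xx - cxs[i]) ** 2
        blob = 100.0 * np.exp(-0.5 * r2 / (radius * 2) ** 2)
        blob[r2 > (radius * 4) ** 2] = 0.0
        rois[r2 <= (radius * 3) ** 2] = i + 1
        blobs.append(blob)

    days = np.arange(1, spec.n_days + 1)
    series_list = []
    jitters = {}
    for group in ("intact", "amputated"):
        for f in range(spec.n_flies_per_group):
            fly_id = f"{group}_{f}"
            jitter = np.zeros((spec.n_days, 2))
            if spec.jitter > 0:
                jitter[1:] = rng.uniform(-spec.jitter, spec.jitter, (spec.n_days - 1, 2))
            images = np.zeros((spec.n_days, h, w))
            for d_idx, day in enumerate(days):
                img = np.zeros((h, w))
                for i, blob in enumerate(blobs):
                    factor = np.exp(-spec.bleach_rate * (day - 1))
                    if (
                        group == "amputated"
                        and (i + 1) in spec.amputated_rois
                        and day >= 2
                    ):
                        factor *= np.exp(-spec.amputation_decay_rate * (day - 2))
                    img += blob * factor
                if np.any(jitter[d_idx] != 0):
                    img = ndimage.shift(img, jitter[d_idx], order=1, mode="constant")
                if spec.noise_sd > 0:
                    img = np.clip(img + rng.normal(0, spec.noise_sd, img.shape), 0, None)
                images[d_idx] = img
            series_list.append(DailySeries(images, days, fly_id, group))
            jitters[fly_id] = jitter

    decay_rates = {}
    for i in range(n):
        decay_rates[("intact", i + 1)] = spec.bleach_rate
        decay_rates[("amputated", i + 1)] = spec.bleach_rate + (
            spec.amputation_decay_rate if (i + 1) in spec.amputated_rois else 0.0
        )
    truth = GroundTruth(
        roi_masks=rois,
        true_decay_rates=decay_rates,
        extras={"jitter": jitters},
    )
    return series_list, truth
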