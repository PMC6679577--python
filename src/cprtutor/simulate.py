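"""Synthetic CPR chest-compression sessions with known ground truth.

The kinematic model is deliberately simple and fully parameterised (it is a
stand-in for real human recordings, not a biomechanical model): each
compression cycle produces a raised-cosine chest displacement pulse whose
peak is the compression depth and whose floor is the residual release
depth.  Hand/wrist joints track the displacement directly, shoulders and
spine track it scaled by a body-weight coupling factor, and elbows dip
below the shoulder-hand line when the arms are not locked.  EMG channels
emit one rectified burst per cycle, amplified when body weight is not used
(arm-muscle compensation), and the accelerometer is the discrete second
derivative of the hand trajectory.

Skeleton coordinates are in metres; displacement ground truth is in mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime
from typing import Sequence

import numpy as np

from .mlt_io import (
    AnnotationInterval,
    AnnotationRecording,
    MLTSession,
    SensorFrame,
    SensorRecording,
)

__all__ = [
    "SimulationParams",
    "GroundTruth",
    "simulate_session",
    "manikin_emulate",
    "KINECT_JOINTS",
]

#: The 15 tracked joints (Kinect-style naming).  Ankles, hips and the head
#: are included on purpose so downstream joint-exclusion rules have material
#: to act on.
KINECT_JOINTS = (
    "Head",
    "SpineMid",
    "SpineBase",
    "ShoulderLeft",
    "ShoulderRight",
    "ElbowLeft",
    "ElbowRight",
    "WristLeft",
    "WristRight",
    "HandLeft",
    "HandRight",
    "HipLeft",
    "HipRight",
    "AnkleLeft",
    "AnkleRight",
)

# Rest pose of the kneeling rescuer, metres, (x, y, z).  Magnitudes are in
# the ~2 m range typical of a depth camera a couple of metres away.
_BASE_POSE = {
    "Head": (0.00, 0.95, 1.95),
    "SpineMid": (0.00, 0.55, 2.00),
    "SpineBase": (0.00, 0.25, 2.05),
    "ShoulderLeft": (-0.18, 0.72, 1.98),
    "ShoulderRight": (0.18, 0.72, 1.98),
    "ElbowLeft": (-0.15, 0.50, 1.90),
    "ElbowRight": (0.15, 0.50, 1.90),
    "WristLeft": (-0.05, 0.30, 1.82),
    "WristRight": (0.05, 0.30, 1.82),
    "HandLeft": (-0.02, 0.26, 1.80),
    "HandRight": (0.02, 0.26, 1.80),
    "HipLeft": (-0.14, 0.20, 2.06),
    "HipRight": (0.14, 0.20, 2.06),
    "AnkleLeft": (-0.16, 0.02, 2.35),
    "AnkleRight": (0.16, 0.02, 2.35),
}

_MM_PER_M = 1000.0


@dataclass
class SimulationParams:
    """Generator settings; every model constant is a named field."""

    rate_cpm: float = 110.0
    depth_mm: float = 55.0
    release_mm: float = 2.0
    arms_locked: bool = True
    body_weight: bool = True
    duration_s: float = 120.0
    rate_jitter_cpm: float = 0.0
    depth_jitter_mm: float = 0.0
    release_jitter_mm: float = 0.0
    sensor_noise_sd: float = 0.0
    kinect_hz: float = 30.0
    myo_hz: float = 100.0
    seed: int = 0
    # --- named model constants (invented, configurable) ---
    #: shoulder/spine displacement coupling when body weight is used
    shoulder_alpha: float = 1.0
    #: coupling when compressing from the arms only
    shoulder_alpha_no_weight: float = 0.3
    #: extra elbow dip (fraction of displacement) when arms are unlocked
    elbow_dip_factor: float = 0.25
    #: EMG burst base amplitude (arbitrary device units)
    emg_amplitude: float = 40.0
    #: EMG gain multiplier when body weight is NOT used
    emg_no_weight_gain: float = 2.0

    def validate(self) -> None:
        positives = {
            "rate_cpm": self.rate_cpm,
            "depth_mm": self.depth_mm,
            "duration_s": self.duration_s,
            "kinect_hz": self.kinect_hz,
            "myo_hz": self.myo_hz,
        }
        for name, value in positives.items():
            if not value > 0:
                raise ValueError(f"{name} must be > 0, got {value}")
        non_negatives = {
            "release_mm": self.release_mm,
            "rate_jitter_cpm": self.rate_jitter_cpm,
            "depth_jitter_mm": self.depth_jitter_mm,
            "release_jitter_mm": self.release_jitter_mm,
            "sensor_noise_sd": self.sensor_noise_sd,
        }
        for name, value in non_negatives.items():
            if value < 0:
                raise ValueError(f"{name} must be >= 0, got {value}")
        if self.duration_s < 60.0 / self.rate_cpm:
            raise ValueError(
                f"duration_s={self.duration_s} too short for one full cycle "
                f"at {self.rate_cpm} compressions/min"
            )


@dataclass
class GroundTruth:
    """Per-compression generator truth in manikin units."""

    intervals: list[AnnotationInterval]
    #: per-cycle (start, end, depth_mm, release_mm) from the generator
    cycles: list[tuple[float, float, float, float]] = field(default_factory=list)
    arms_locked: bool = True
    body_weight: bool = True

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def boundaries(self) -> np.ndarray:
        """Cycle edge times: starts of every cycle plus the final end."""
        if not self.cycles:
            return np.empty(0)
        return np.array([c[0] for c in self.cycles] + [self.cycles[-1][1]])


def _draw_cycles(params: SimulationParams, rng: np.random.Generator):
    """Sequential per-compression cycles with jittered rate/depth/release."""
    cycles = []
    t = 0.0
    while True:
        rate = params.rate_cpm + rng.normal(0.0, params.rate_jitter_cpm) if params.rate_jitter_cpm else params.rate_cpm
        rate = max(rate, 10.0)
        period = 60.0 / rate
        if t + period > params.duration_s + 1e-9:
            break
        depth = params.depth_mm + (
            rng.normal(0.0, params.depth_jitter_mm) if params.depth_jitter_mm else 0.0
        )
        depth = max(depth, 1.0)
        release = params.release_mm + (
            rng.normal(0.0, params.release_jitter_mm) if params.release_jitter_mm else 0.0
        )
        release = float(np.clip(release, 0.0, 0.9 * depth))
        cycles.append((t, t + period, depth, release))
        t += period
    if not cycles:
        raise ValueError("duration too short for one full cycle")
    return cycles


def _displacement(times: np.ndarray, cycles) -> np.ndarray:
    """Chest displacement in mm at ``times`` for the given cycles.

    Within a cycle of period T the pulse is
    ``release + (depth - release) * (1 - cos(2*pi*tau/T)) / 2``:
    it starts and ends at the residual release depth and peaks at the
    compression depth mid-cycle.  Outside all cycles the chest rests at the
    neighbouring cycle's release depth.
    """
    starts = np.array([c[0] for c in cycles])
    out = np.empty_like(times, dtype=float)
    idx = np.searchsorted(starts, times, side="right") - 1
    idx = np.clip(idx, 0, len(cycles) - 1)
    for k in range(len(cycles)):
        sel = idx == k
        if not sel.any():
            continue
        start, end, depth, release = cycles[k]
        tau = np.clip(times[sel] - start, 0.0, end - start)
        period = end - start
        out[sel] = release + (depth - release) * 0.5 * (1.0 - np.cos(2.0 * np.pi * tau / period))
    return out


def _kinect_recording(params: SimulationParams, cycles, rng: np.random.Generator) -> SensorRecording:
    n = int(np.floor(params.duration_s * params.kinect_hz)) + 1
    times = np.arange(n) / params.kinect_hz
    times = times[times <= params.duration_s + 1e-12]
    d_m = _displacement(times, cycles) / _MM_PER_M

    alpha = params.shoulder_alpha if params.body_weight else params.shoulder_alpha_no_weight
    dip = 0.0 if params.arms_locked else params.elbow_dip_factor

    traces: dict[str, np.ndarray] = {}
    for joint in KINECT_JOINTS:
        bx, by, bz = _BASE_POSE[joint]
        if joint.startswith(("Hand", "Wrist")):
            y = by - d_m
        elif joint.startswith("Shoulder") or joint in ("SpineMid", "SpineBase"):
            y = by - alpha * d_m
        elif joint.startswith("Elbow"):
            side = joint.removeprefix("Elbow")
            sy = _BASE_POSE[f"Shoulder{side}"][1]
            hy = _BASE_POSE[f"Hand{side}"][1]
            # midpoint of the (moving) shoulder-hand segment, plus an extra
            # dip proportional to displacement when the arms are unlocked
            y = 0.5 * ((sy - alpha * d_m) + (hy - d_m)) - dip * d_m
        else:  # Head, Hips, Ankles: static
            y = np.full_like(d_m, by)
        traces[f"Kinect.{joint}X"] = np.full_like(d_m, bx)
        traces[f"Kinect.{joint}Y"] = y
        traces[f"Kinect.{joint}Z"] = np.full_like(d_m, bz)
        traces[f"Kinect.{joint}State"] = np.full_like(d_m, 2.0)

    if params.sensor_noise_sd:
        for name, values in traces.items():
            if not name.endswith("State"):
                traces[name] = values + rng.normal(0.0, params.sensor_noise_sd, values.shape)

    names = list(traces)
    frames = [
        SensorFrame(
            timestamp=float(t),
            attributes={name: float(traces[name][i]) for name in names},
        )
        for i, t in enumerate(times)
    ]
    return SensorRecording("kinect-sim", "Kinect", frames)


def _myo_recording(params: SimulationParams, cycles, rng: np.random.Generator) -> SensorRecording:
    n = int(np.floor(params.duration_s * params.myo_hz)) + 1
    times = np.arange(n) / params.myo_hz
    times = times[times <= params.duration_s + 1e-12]
    d_mm = _displacement(times, cycles)
    d_m = d_mm / _MM_PER_M
    dt = 1.0 / params.myo_hz

    # burst shape: squared raised cosine, one burst per compression cycle
    starts = np.array([c[0] for c in cycles])
    idx = np.clip(np.searchsorted(starts, times, side="right") - 1, 0, len(cycles) - 1)
    phase = np.empty_like(times)
    for k in range(len(cycles)):
        sel = idx == k
        if sel.any():
            start, end, _, _ = cycles[k]
            phase[sel] = (times[sel] - start) / (end - start)
    burst = (0.5 * (1.0 - np.cos(2.0 * np.pi * np.clip(phase, 0.0, 1.0)))) ** 2
    gain = params.emg_amplitude * (1.0 if params.body_weight else params.emg_no_weight_gain)

    hand_y = _BASE_POSE["HandRight"][1] - d_m
    acc_y = np.gradient(np.gradient(hand_y, dt), dt)
    vel_y = np.gradient(hand_y, dt)

    noise = params.sensor_noise_sd
    traces: dict[str, np.ndarray] = {}
    for pod in range(8):
        pod_gain = 0.6 + 0.05 * pod
        emg = gain * pod_gain * burst
        if noise:
            emg = emg + rng.normal(0.0, noise, emg.shape)
        traces[f"Myo.EMGPod{pod}"] = np.abs(emg)  # rectified
    traces["Myo.AccX"] = rng.normal(0.0, noise, times.shape) if noise else np.zeros_like(times)
    traces["Myo.AccY"] = acc_y + (rng.normal(0.0, noise, times.shape) if noise else 0.0)
    traces["Myo.AccZ"] = rng.normal(0.0, noise, times.shape) if noise else np.zeros_like(times)
    traces["Myo.GyrX"] = vel_y * 50.0 + (rng.normal(0.0, noise, times.shape) if noise else 0.0)
    traces["Myo.GyrY"] = rng.normal(0.0, noise, times.shape) if noise else np.zeros_like(times)
    traces["Myo.GyrZ"] = rng.normal(0.0, noise, times.shape) if noise else np.zeros_like(times)
    traces["Myo.OriW"] = 1.0 - 0.05 * d_m + (rng.normal(0.0, noise, times.shape) if noise else 0.0)
    traces["Myo.OriX"] = 0.1 * d_m + (rng.normal(0.0, noise, times.shape) if noise else 0.0)
    traces["Myo.OriY"] = -0.2 * d_m + (rng.normal(0.0, noise, times.shape) if noise else 0.0)
    traces["Myo.OriZ"] = rng.normal(0.0, noise, times.shape) if noise else np.zeros_like(times)

    names = list(traces)
    frames = [
        SensorFrame(
            timestamp=float(t),
            attributes={name: float(traces[name][i]) for name in names},
        )
        for i, t in enumerate(times)
    ]
    return SensorRecording("myo-sim", "Myo", frames)


def manikin_emulate(
    trace_times: np.ndarray,
    trace_mm: np.ndarray,
    cycle_boundaries: Sequence[float],
) -> list[dict[str, float]]:
    """Derive per-compression measurements from a displacement trace.

    For each cycle ``[b_i, b_{i+1})``: ``compDepth`` is the peak
    displacement, ``compMeanRate`` is ``60 / (b_{i+1} - b_i)`` and
    ``compRelease`` is the minimum displacement between the peak and the
    next compression onset.  Returns one dict per complete cycle; fewer
    than one cycle yields an empty list.
    """
    trace_times = np.asarray(trace_times, dtype=float)
    trace_mm = np.asarray(trace_mm, dtype=float)
    boundaries = np.asarray(cycle_boundaries, dtype=float)
    if boundaries.size < 2:
        return []
    # the final boundary is exclusive: the trace only needs samples up to
    # one sample period short of it
    if trace_times.size > 1:
        sample_period = (trace_times[-1] - trace_times[0]) / (trace_times.size - 1)
    else:
        sample_period = np.inf
    if (
        trace_times[0] > boundaries[0] + 1e-9
        or trace_times[-1] < boundaries[-1] - sample_period - 1e-9
    ):
        raise ValueError("displacement trace does not cover all cycles")
    out: list[dict[str, float]] = []
    for i in range(boundaries.size - 1):
        start, end = boundaries[i], boundaries[i + 1]
        lo = np.searchsorted(trace_times, start, side="left")
        hi = np.searchsorted(trace_times, end, side="left")
        if hi <= lo:
            continue
        segment = trace_mm[lo:hi]
        peak_off = int(np.argmax(segment))
        depth = float(segment[peak_off])
        release = float(np.min(segment[peak_off:]))
        out.append(
            {
                "compDepth": depth,
                "compMeanRate": float(60.0 / (end - start)),
                "compRelease": release,
            }
        )
    return out


def simulate_session(
    params: SimulationParams,
    session_id: str = "sim-session",
    recording_datetime: datetime | None = None,
) -> tuple[MLTSession, GroundTruth]:
    """Generate one synthetic session and its ground truth.

    The session contains a Kinect-style and a Myo-style sensor recording
    plus a manikin-style annotation recording whose measurements come from
    :func:`manikin_emulate` run on the noise-free displacement trace (the
    "SimPad" role).  The returned :class:`GroundTruth` holds the
    generator's own per-cycle values, which the emulated measurements can
    be validated against.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    cycles = _draw_cycles(params, rng)

    kinect = _kinect_recording(params, cycles, rng)
    myo = _myo_recording(params, cycles, rng)

    # dense, noise-free displacement trace for the manikin emulator
    dense_hz = max(4.0 * params.myo_hz, 200.0)
    dense_t = np.arange(int(np.floor(params.duration_s * dense_hz)) + 1) / dense_hz
    dense_d = _displacement(dense_t, cycles)
    boundaries = [c[0] for c in cycles] + [cycles[-1][1]]
    measured = manikin_emulate(dense_t, dense_d, boundaries)

    flags = {"armsLocked": int(params.arms_locked), "bodyWeight": int(params.body_weight)}
    annotation = AnnotationRecording(
        "manikin-sim",
        "Annotation",
        intervals=[
            AnnotationInterval(
                start=cycles[i][0],
                end=cycles[i][1],
                measurements=m,
                labels=dict(flags),
            )
            for i, m in enumerate(measured)
        ],
    )
    truth = GroundTruth(
        intervals=[
            AnnotationInterval(
                start=start,
                end=end,
                measurements={
                    "compDepth": depth,
                    "compMeanRate": 60.0 / (end - start),
                    "compRelease": release,
                },
                labels=dict(flags),
            )
            for start, end, depth, release in cycles
        ],
        cycles=list(cycles),
        arms_locked=params.arms_locked,
        body_weight=params.body_weight,
    )
    session = MLTSession(
        session_id=session_id,
        recording_datetime=recording_datetime or datetime(2019, 1, 1),
        sensor_recordings=[kinect, myo],
        annotation_recordings=[annotation],
    )
    return session, truth
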