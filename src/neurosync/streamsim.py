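"""Multi-device session simulator.

Several wireless devices (accelerometers, EEG front-ends) observe the same
physical scene — a rigid panel that is shaken and struck — but each device
stamps its samples with its own imperfect clock and ships them over a wireless
hop that adds a constant, per-startup transport delay.  This module builds
such sessions from first principles so that the synchronization and
calibration stages can be tested against exact ground truth.

Clock model
-----------
A device clock reads ``raw_t = t * (1 + drift) + offset0 + jitter`` where
``t`` is the shared reference (recorder) time, ``drift`` is the fractional
rate error (ppm scale), ``offset0`` the boot-time offset and ``jitter``
per-sample timestamp noise.  Independently of the clock, the *content* of the
stream is delayed by a transport latency that the clock-synchronization
protocol cannot see; it is redrawn at every cold start and is exactly what
the perturbation calibration estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ClockModel",
    "DeviceSpec",
    "PerturbationProfile",
    "SimulatedStream",
    "SimSession",
    "simulate_motion",
    "sample_stream",
    "simulate_session",
]

REFERENCE_RATE = 1000.0  # Hz, rate of the ground-truth motion trace


@dataclass(frozen=True)
class ClockModel:
    """Per-device clock imperfections and wireless transport delay.

    Parameters
    ----------
    offset0 : float
        Initial clock offset versus the shared reference, seconds.
    drift : float
        Fractional clock-rate error (dimensionless; 1e-6 == 1 ppm).
    jitter_sd : float
        Per-sample timestamp noise standard deviation, seconds.
    transport_latency : float
        Mean wireless content delay, seconds.  Redrawn at each startup.
    transport_latency_sd : float
        Across-startup standard deviation of the transport latency, seconds.
    """

    offset0: float = 0.0
    drift: float = 0.0
    jitter_sd: float = 0.0
    transport_latency: float = 0.0
    transport_latency_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")
        if self.transport_latency_sd < 0:
            raise ValueError("transport_latency_sd must be >= 0")
        if abs(self.drift) >= 1e-3:
            raise ValueError("|drift| must be < 1000 ppm")

    def offset_at(self, t: np.ndarray | float) -> np.ndarray | float:
        """True clock offset (raw − reference) at reference time ``t``."""
        return self.offset0 + self.drift * np.asarray(t, dtype=float)


@dataclass(frozen=True)
class DeviceSpec:
    """Identity and sampling/loss behaviour of one device."""

    name: str
    nominal_rate: float
    channel_labels: tuple[str, ...] = ("acc_x", "acc_y", "acc_z")
    loss_rate: float = 0.0          # probability per sample of starting a lost run
    loss_run_mean: float = 5.0      # geometric mean run length, samples

    def __post_init__(self) -> None:
        if self.nominal_rate <= 0:
            raise ValueError("nominal_rate must be positive")
        if not 0.0 <= self.loss_rate < 1.0:
            raise ValueError("loss_rate must be in [0, 1)")
        if self.loss_run_mean < 1:
            raise ValueError("loss_run_mean must be >= 1 sample")


@dataclass(frozen=True)
class PerturbationProfile:
    """Schedule of mechanical perturbations applied to the shared rig.

    Strokes are short impulsive taps; movement windows are intervals of
    band-limited random shaking.  Both ride on Gaussian baseline noise.
    """

    n_strokes: int = 0
    stroke_width: float = 0.05          # seconds
    stroke_amplitude: float = 10.0      # m/s^2
    stroke_times: tuple[float, ...] | None = None
    movement_windows: tuple[tuple[float, float], ...] = ()
    movement_bandwidth: float = 10.0    # Hz
    movement_amplitude: float = 5.0     # m/s^2 rms per axis
    baseline_noise_sd: float = 0.05     # m/s^2

    def __post_init__(self) -> None:
        if self.n_strokes > 0 and self.baseline_noise_sd > 0:
            if self.stroke_amplitude <= 5 * self.baseline_noise_sd:
                raise ValueError(
                    "stroke_amplitude must exceed 5 x baseline_noise_sd")

    def validate_against(self, duration: float) -> None:
        if self.stroke_times is not None:
            for t in self.stroke_times:
                if not (0.0 <= t - self.stroke_width
                        and t + self.stroke_width <= duration):
                    raise ValueError(
                        f"stroke at {t:.3f} s falls outside the "
                        f"{duration:.3f} s session")
        for start, end in self.movement_windows:
            if not (0.0 <= start < end <= duration):
                raise ValueError(
                    f"movement window ({start}, {end}) outside the session")


@dataclass
class SimulatedStream:
    """One device's view of the session."""

    device: DeviceSpec
    samples: np.ndarray          # channels x n
    raw_timestamps: np.ndarray   # seconds, device clock
    lost_mask: np.ndarray        # bool per sample
    clock_offset_history: np.ndarray  # (m, 2): measurement_time, measured_offset
    clock: ClockModel | None = None   # ground truth, absent for external files
    shared_timestamps: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def synchronizable(self) -> bool:
        """A stream without an offset history cannot be remapped."""
        return self.clock_offset_history.shape[0] >= 2


@dataclass
class SimSession:
    """A set of simulated streams plus exact ground truth."""

    streams: list[SimulatedStream]
    duration: float
    seed: int
    ground_truth_latencies: dict[str, float]  # device name -> drawn latency (s)
    clocks: dict[str, ClockModel]
    motion: np.ndarray | None = None  # 3 x n reference trace (1 kHz)

    @property
    def device_names(self) -> list[str]:
        return [s.device.name for s in self.streams]

    def true_offset_matrix_ms(self) -> np.ndarray:
        """Pairwise ground-truth content offsets in ms.

        Entry (i, j) is the delay of device j's content relative to device
        i's: latency_j − latency_i.  Antisymmetric and additive by
        construction.
        """
        lat = np.array([self.ground_truth_latencies[n]
                        for n in self.device_names])
        return (lat[None, :] - lat[:, None]) * 1e3


def simulate_motion(profile: PerturbationProfile, duration: float,
                    rate: float = REFERENCE_RATE, seed: int = 0) -> np.ndarray:
    """Build the 3-axis ground-truth acceleration trace.

    Returns an array of shape (3, round(duration*rate)) sampled on the grid
    ``np.arange(n) / rate``.  Deterministic for a given seed.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if rate < 2 * profile.movement_bandwidth:
        raise ValueError("rate must be at least twice the movement bandwidth")
    profile.validate_against(duration)

    rng = np.random.default_rng(seed)
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    trace = np.zeros((3, n))

    if profile.baseline_noise_sd > 0:
        trace += rng.normal(0.0, profile.baseline_noise_sd, size=(3, n))

    # Band-limited shaking inside movement windows: low-passed white noise,
    # rescaled to the requested per-axis rms, faded in/out over 50 ms.
    from scipy.signal import butter, sosfiltfilt

    if profile.movement_windows:
        sos = butter(4, profile.movement_bandwidth, btype="low",
                     fs=rate, output="sos")
        for start, end in profile.movement_windows:
            i0, i1 = int(round(start * rate)), int(round(end * rate))
            seg = rng.normal(0.0, 1.0, size=(3, i1 - i0))
            seg = sosfiltfilt(sos, seg, axis=1)
            rms = np.sqrt(np.mean(seg ** 2, axis=1, keepdims=True))
            seg = seg / np.maximum(rms, 1e-30) * profile.movement_amplitude
            ramp_n = min(int(0.05 * rate), (i1 - i0) // 2)
            if ramp_n > 0:
                w = np.ones(i1 - i0)
                ramp = 0.5 * (1 - np.cos(np.pi * np.arange(ramp_n) / ramp_n))
                w[:ramp_n] = ramp
                w[-ramp_n:] = ramp[::-1]
                seg *= w
            trace[:, i0:i1] += seg

    # Impulsive strokes: biphasic Gaussian-derivative pulse on a random axis
    # direction, dominated by a sharp positive lobe of width stroke_width.
    if profile.n_strokes > 0:
        if profile.stroke_times is not None:
            times = np.asarray(profile.stroke_times, dtype=float)
            if len(times) != profile.n_strokes:
                raise ValueError("stroke_times length must equal n_strokes")
        else:
            lo = 2 * profile.stroke_width
            hi = duration - 2 * profile.stroke_width
            if hi <= lo:
                raise ValueError("session too short for the stroke width")
            times = np.sort(rng.uniform(lo, hi, size=profile.n_strokes))
        half = profile.stroke_width
        for t0 in times:
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            sel = (t >= t0 - 3 * half) & (t <= t0 + 3 * half)
            tau = (t[sel] - t0) / half
            pulse = profile.stroke_amplitude * np.exp(-0.5 * tau ** 2) \
                * (1.0 - 0.35 * tau)
            trace[:, sel] += direction[:, None] * pulse[None, :]

    return trace


def _draw_lost_mask(n: int, device: DeviceSpec, rng: np.random.Generator
                    ) -> np.ndarray:
    """Geometric-run packet-loss process.

    Each sample outside a run starts a run with probability ``loss_rate``;
    run lengths are geometric with mean ``loss_run_mean``.
    """
    mask = np.zeros(n, dtype=bool)
    if device.loss_rate <= 0:
        return mask
    p_run = 1.0 / device.loss_run_mean
    starts = rng.random(n) < device.loss_rate
    lengths = rng.geometric(p_run, size=n)
    i = 0
    while i < n:
        if starts[i]:
            run = lengths[i]
            mask[i:i + run] = True
            i += run
        else:
            i += 1
    return mask


def sample_stream(motion: np.ndarray, device: DeviceSpec, clock: ClockModel,
                  seed: int = 0, *, motion_rate: float = REFERENCE_RATE,
                  transport_latency: float | None = None,
                  offset_interval: float = 5.0,
                  offset_noise_sd: float = 0.2e-3) -> SimulatedStream:
    """Sample the ground-truth motion the way one device would.

    The device samples at ``nominal_rate`` on the reference grid; content is
    delayed by the transport latency (so features appear *later* in this
    stream); raw timestamps are produced by the clock model; clock-offset
    measurements are logged every ``offset_interval`` seconds with Gaussian
    measurement noise (the out-of-band synchronization channel).

    Pass ``transport_latency`` to pin the per-startup draw; otherwise it is
    drawn Normal(clock.transport_latency, clock.transport_latency_sd),
    truncated at zero.
    """
    if device.nominal_rate <= 0:
        raise ValueError("nominal_rate must be positive")
    motion = np.atleast_2d(np.asarray(motion, dtype=float))
    rng = np.random.default_rng(seed)

    duration = motion.shape[1] / motion_rate
    if transport_latency is None:
        transport_latency = max(
            0.0, rng.normal(clock.transport_latency, clock.transport_latency_sd))

    n = int(round(duration * device.nominal_rate))
    t_ref = np.arange(n) / device.nominal_rate

    # Content delayed by the transport hop: the value stamped at reference
    # time t was produced at t - latency.
    src_t = np.arange(motion.shape[1]) / motion_rate
    samples = np.empty((motion.shape[0], n))
    for ch in range(motion.shape[0]):
        samples[ch] = np.interp(t_ref - transport_latency, src_t, motion[ch],
                                left=0.0, right=0.0)

    raw = t_ref * (1.0 + clock.drift) + clock.offset0
    if clock.jitter_sd > 0:
        raw = raw + rng.normal(0.0, clock.jitter_sd, size=n)
        # keep timestamps strictly increasing, as real recorders guarantee
        raw = np.maximum.accumulate(raw + np.arange(n) * 1e-12)

    lost = _draw_lost_mask(n, device, rng)
    samples[:, lost] = np.nan

    m_times = np.arange(0.0, duration + 1e-9, offset_interval)
    if len(m_times) < 2 or m_times[-1] < duration:
        m_times = np.unique(np.append(m_times, duration))
    measured = clock.offset_at(m_times)
    if offset_noise_sd > 0:
        measured = measured + rng.normal(0.0, offset_noise_sd, size=len(m_times))
    history = np.column_stack([m_times, measured])

    return SimulatedStream(
        device=device, samples=samples, raw_timestamps=raw, lost_mask=lost,
        clock_offset_history=history,
        clock=replace(clock, transport_latency=transport_latency),
        meta={"transport_latency": float(transport_latency)},
    )


def simulate_session(devices: list[DeviceSpec], clocks: dict[str, ClockModel],
                     profile: PerturbationProfile, duration: float,
                     seed: int = 0, *, offset_interval: float = 5.0,
                     offset_noise_sd: float = 0.2e-3) -> SimSession:
    """One cold-start acquisition: all devices see the same motion, each with
    its own clock and a freshly drawn transport latency."""
    ss = np.random.SeedSequence(seed)
    child = ss.spawn(len(devices) + 1)
    motion = simulate_motion(profile, duration,
                             seed=child[0].generate_state(1)[0] % (2 ** 31))

    streams: list[SimulatedStream] = []
    latencies: dict[str, float] = {}
    for dev, cs in zip(devices, child[1:]):
        clock = clocks[dev.name]
        stream = sample_stream(
            motion, dev, clock, seed=cs.generate_state(1)[0] % (2 ** 31),
            offset_interval=offset_interval, offset_noise_sd=offset_noise_sd)
        streams.append(stream)
        latencies[dev.name] = stream.meta["transport_latency"]

    return SimSession(streams=streams, duration=duration, seed=seed,
                      ground_truth_latencies=latencies,
                      clocks={d.name: clocks[d.name] for d in devices},
                      motion=motion)
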