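"""Synthetic 7-channel EEG sessions for the four validation tasks.

Recordings are built at 500 Hz on the montage Fpz, Fz, Cz, Pz, Oz, C3, C4
(earlobe-referenced wearable layout).  Background activity is 1/f ("pink")
noise plus a white floor, scaled per device profile; each task adds its
physiological signature at the physiologically correct channels:

* eyes open/closed — occipital alpha (10 Hz) at Oz/Pz whose amplitude rises
  with eye closure (alpha reactivity);
* motor — a 10–20 Hz sensorimotor rhythm at C3/C4/Cz that desynchronizes
  (power drops by ``erd_fraction``) during movement;
* ssvep — an occipital oscillation at twice the checkerboard modulation
  frequency (pattern-reversal doubling);
* oddball — a positive Cz/Pz deflection peaking 250–400 ms after rare target
  stimuli (the P300).

Artifacts (blinks, lost-sample runs, amplitude excursions, linear drift) are
injected separately so rejection rules can be tested against an exact
injection log.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CHANNELS",
    "SFREQ",
    "TaskProtocol",
    "EffectSpec",
    "DeviceProfile",
    "Recording",
    "gen_oddball_sequence",
    "gen_carousel_run",
    "synth_task_recording",
    "inject_artifacts",
    "inject_lost_run",
    "inject_amplitude_artifact",
    "inject_ramp",
]

CHANNELS = ("Fpz", "Fz", "Cz", "Pz", "Oz", "C3", "C4")
SFREQ = 500.0
BLINK_PERIOD_S = 60.0  # free-blinking lead-in used for blink identification

# Scalp gradient of the ocular artifact: maximal at the forehead, nearly
# absent occipitally.
_BLINK_TOPO = {"Fpz": 1.0, "Fz": 0.55, "Cz": 0.30, "Pz": 0.12,
               "Oz": 0.04, "C3": 0.25, "C4": 0.25}


@dataclass(frozen=True)
class TaskProtocol:
    """Trial structure of one validation task."""

    task: str                      # eyes | motor | ssvep | oddball
    n_repetitions: int = 0
    state_duration: float = 5.0    # eyes: seconds per open/closed state
    move_duration: float = 4.0     # motor
    rest_range: tuple[float, float] = (8.0, 12.0)
    ssvep_frequencies: tuple[float, ...] = (5.0, 6.0)
    n_runs: int = 3                # ssvep runs per frequency / oddball runs
    trial_duration: float = 10.0   # ssvep
    rest_duration: float = 7.0     # ssvep inter-trial rest
    n_targets_range: tuple[int, int] = (10, 12)
    stimulus_duration: float = 0.200
    isi: float = 0.400

    @staticmethod
    def eyes() -> "TaskProtocol":
        return TaskProtocol(task="eyes", n_repetitions=10)

    @staticmethod
    def motor() -> "TaskProtocol":
        return TaskProtocol(task="motor", n_repetitions=25)

    @staticmethod
    def ssvep() -> "TaskProtocol":
        return TaskProtocol(task="ssvep", n_runs=3)

    @staticmethod
    def oddball() -> "TaskProtocol":
        return TaskProtocol(task="oddball", n_runs=5)


@dataclass(frozen=True)
class EffectSpec:
    """Amplitudes and rates of the synthesized neural features and artifacts.

    Defaults are realistic scalp values: a few µV of occipital alpha with
    clear eyes-closed reactivity, ~50% sensorimotor desynchronization, a
    single-µV SSVEP line and a mid-size P300 against ~4 µV rms broadband
    background.
    """

    alpha_open_uv: float = 1.5
    alpha_closed_uv: float = 5.0
    erd_fraction: float = 0.5        # relative power drop during movement
    smr_uv: float = 4.0              # baseline sensorimotor rhythm amplitude
    ssvep_uv: float = 3.0
    p300_uv: float = 6.0
    p300_latency_ms: float = 320.0
    p300_width_ms: float = 60.0      # Gaussian sd of the deflection
    background_noise_uv: float = 4.0  # broadband rms (pink + white)
    blink_rate_hz: float = 0.25
    blink_amplitude_uv: float = 120.0
    loss_rate: float = 2e-4          # per-sample probability of a lost run
    loss_run_mean: float = 8.0
    amp_artifact_rate_hz: float = 0.01
    amp_artifact_uv: float = 80.0
    drift_rate_hz: float = 0.0       # random ramp segments (off by default)
    drift_uv_per_s: float = 15.0

    def __post_init__(self) -> None:
        if not 250.0 <= self.p300_latency_ms <= 400.0:
            raise ValueError("p300_latency_ms must lie in [250, 400] ms")
        if self.alpha_closed_uv <= self.alpha_open_uv:
            raise ValueError("positive reactivity requires "
                             "alpha_closed_uv > alpha_open_uv")


@dataclass(frozen=True)
class DeviceProfile:
    """Noise/loss character of an acquisition system.

    ``lab_grade`` mimics a low-noise wet-electrode laboratory system;
    ``wearable_dry`` a dry-electrode wireless headset with a higher noise
    floor and wireless packet loss.
    """

    name: str
    noise_multiplier: float
    loss_enabled: bool

    @staticmethod
    def lab_grade() -> "DeviceProfile":
        return DeviceProfile("lab_grade", 1.0, False)

    @staticmethod
    def wearable_dry() -> "DeviceProfile":
        return DeviceProfile("wearable_dry", 2.0, True)


@dataclass
class Recording:
    """Continuous multichannel EEG with event markers and a lost-sample mask."""

    data: np.ndarray                     # channels x n, µV
    sfreq: float
    ch_names: tuple[str, ...]
    events: list[tuple[float, str]]      # (onset seconds, label)
    lost_mask: np.ndarray                # bool per sample
    blink_period: tuple[float, float] = (0.0, BLINK_PERIOD_S)
    meta: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sfreq

    def channel(self, name: str) -> np.ndarray:
        return self.data[self.ch_names.index(name)]

    def copy(self) -> "Recording":
        return Recording(data=self.data.copy(), sfreq=self.sfreq,
                         ch_names=self.ch_names, events=list(self.events),
                         lost_mask=self.lost_mask.copy(),
                         blink_period=self.blink_period, meta=dict(self.meta))


def gen_oddball_sequence(n_targets: int, ratio: float | None = None,
                         seed: int = 0) -> list[str]:
    """Randomized oddball stimulus sequence with no two consecutive targets.

    By default the non-target count follows the protocol pairing
    ``non_targets = 6 * n_targets`` (10 targets ↔ 60 non-targets).  An
    explicit ``ratio`` (targets / non-targets) overrides it; non-integer
    counts are rounded with a warning.
    """
    if n_targets < 1:
        raise ValueError("n_targets must be >= 1")
    if ratio is None:
        n_non = 6 * n_targets
    else:
        if not 0.0 < ratio < 1.0:
            raise ValueError("ratio must lie in (0, 1)")
        exact = n_targets / ratio - n_targets
        n_non = int(round(exact))
        if abs(exact - n_non) > 1e-9:
            warnings.warn(f"ratio {ratio} gives non-integer non-target count "
                          f"{exact:.2f}; rounded to {n_non}")
    if n_non < n_targets - 1:
        raise ValueError("too few non-targets to avoid consecutive targets")

    rng = np.random.default_rng(seed)
    # place targets into distinct gaps between/around non-targets: this makes
    # consecutive targets impossible and the order otherwise uniform
    gaps = rng.choice(n_non + 1, size=n_targets, replace=False)
    seq: list[str] = []
    gap_set = set(int(g) for g in gaps)
    for i in range(n_non + 1):
        if i in gap_set:
            seq.append("target")
        if i < n_non:
            seq.append("nontarget")
    return seq


def gen_carousel_run(n_icons: int = 6, n_repetitions: int = 3,
                     seed: int = 0) -> list[str]:
    """One menu-carousel run: each of ``n_icons`` icons shown
    ``n_repetitions`` times in random order, one icon being the target."""
    rng = np.random.default_rng(seed)
    target_icon = int(rng.integers(n_icons))
    icons = np.repeat(np.arange(n_icons), n_repetitions)
    rng.shuffle(icons)
    return ["target" if i == target_icon else "nontarget" for i in icons]


def _pink_noise(rng: np.random.Generator, shape: tuple[int, int],
                sfreq: float) -> np.ndarray:
    """Gaussian noise with a 1/f power spectrum, unit variance per channel."""
    n_ch, n = shape
    white = rng.normal(size=(n_ch, n))
    spec = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(n, 1.0 / sfreq)
    scale = np.ones_like(f)
    nz = f > 0
    scale[nz] = 1.0 / np.sqrt(f[nz])
    scale[0] = 0.0
    pink = np.fft.irfft(spec * scale[None, :], n=n, axis=1)
    pink /= pink.std(axis=1, keepdims=True)
    return pink


def _background(rng: np.random.Generator, n: int, effects: EffectSpec,
                device: DeviceProfile) -> np.ndarray:
    level = effects.background_noise_uv * device.noise_multiplier
    pink = _pink_noise(rng, (len(CHANNELS), n), SFREQ)
    white = rng.normal(size=(len(CHANNELS), n))
    # 80% of background power in the 1/f part, 20% white floor
    return level * (np.sqrt(0.8) * pink + np.sqrt(0.2) * white)


def _osc(t: np.ndarray, freq: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-amplitude oscillation with a random phase and slow amplitude
    fluctuation, so narrow-band features are not perfectly deterministic."""
    phase = rng.uniform(0, 2 * np.pi)
    am = 1.0 + 0.2 * np.sin(2 * np.pi * rng.uniform(0.05, 0.15) * t
                            + rng.uniform(0, 2 * np.pi))
    return am * np.sin(2 * np.pi * freq * t + phase)


def _smooth_gate(n: int, intervals: list[tuple[int, int]],
                 sfreq: float, ramp_s: float = 0.25) -> np.ndarray:
    """0/1 envelope over the listed sample intervals with cosine ramps."""
    gate = np.zeros(n)
    for a, b in intervals:
        gate[a:b] = 1.0
    ramp_n = int(ramp_s * sfreq)
    if ramp_n > 1:
        from scipy.ndimage import uniform_filter1d

        gate = uniform_filter1d(gate, size=ramp_n, mode="nearest")
    return gate


def synth_task_recording(protocol: TaskProtocol, effects: EffectSpec,
                         device: DeviceProfile, seed: int = 0) -> Recording:
    """Synthesize one clean task recording (no artifacts).

    The session starts with a 60 s free-blinking baseline (blinks themselves
    are added by :func:`inject_artifacts`), followed by the task trials.
    Event markers carry condition labels at stimulus/state onsets.
    """
    rng = np.random.default_rng(seed)
    events: list[tuple[float, str]] = []
    idx = {c: i for i, c in enumerate(CHANNELS)}

    if protocol.task == "eyes":
        duration = BLINK_PERIOD_S + 2 * protocol.state_duration * protocol.n_repetitions + 2.0
        n = int(duration * SFREQ)
        t = np.arange(n) / SFREQ
        data = _background(rng, n, effects, device)
        closed_iv, cursor = [], BLINK_PERIOD_S
        for _ in range(protocol.n_repetitions):
            events.append((cursor, "closed"))
            closed_iv.append((int(cursor * SFREQ),
                              int((cursor + protocol.state_duration) * SFREQ)))
            cursor += protocol.state_duration
            events.append((cursor, "open"))
            cursor += protocol.state_duration
        gate = _smooth_gate(n, closed_iv, SFREQ)
        amp = effects.alpha_open_uv + (effects.alpha_closed_uv
                                       - effects.alpha_open_uv) * gate
        alpha = _osc(t, 10.0, rng)
        data[idx["Oz"]] += amp * alpha
        data[idx["Pz"]] += 0.6 * amp * _osc(t, 10.0, rng)

    elif protocol.task == "motor":
        rests = rng.uniform(*protocol.rest_range, size=protocol.n_repetitions)
        duration = BLINK_PERIOD_S + float(
            np.sum(rests + protocol.move_duration)) + 8.0
        n = int(duration * SFREQ)
        t = np.arange(n) / SFREQ
        data = _background(rng, n, effects, device)
        move_iv, cursor = [], BLINK_PERIOD_S + 6.0  # lead-in so ERSP baselines fit
        for k in range(protocol.n_repetitions):
            events.append((cursor, "move"))
            move_iv.append((int(cursor * SFREQ),
                            int((cursor + protocol.move_duration) * SFREQ)))
            cursor += protocol.move_duration
            events.append((cursor, "rest"))
            cursor += float(rests[k])
        gate = _smooth_gate(n, move_iv, SFREQ)
        # sensorimotor rhythm: mu (11 Hz) + beta (19 Hz), attenuated in power
        # by erd_fraction while moving -> amplitude x sqrt(1 - erd)
        att = np.sqrt(1.0 - effects.erd_fraction * gate)
        for ch in ("C3", "C4", "Cz"):
            smr = effects.smr_uv * (0.75 * _osc(t, 11.0, rng)
                                    + 0.55 * _osc(t, 19.0, rng))
            data[idx[ch]] += att * smr

    elif protocol.task == "ssvep":
        block = protocol.trial_duration + protocol.rest_duration
        duration = BLINK_PERIOD_S + block * protocol.n_runs * len(
            protocol.ssvep_frequencies) + 2.0
        n = int(duration * SFREQ)
        t = np.arange(n) / SFREQ
        data = _background(rng, n, effects, device)
        cursor = BLINK_PERIOD_S
        order = [f for f in protocol.ssvep_frequencies
                 for _ in range(protocol.n_runs)]
        for f_mod in order:
            events.append((cursor, f"ssvep_{f_mod:g}"))
            a = int(cursor * SFREQ)
            b = int((cursor + protocol.trial_duration) * SFREQ)
            gate = _smooth_gate(n, [(a, b)], SFREQ, ramp_s=0.1)
            # pattern reversal drives the cortex at twice the modulation rate
            data[idx["Oz"]] += effects.ssvep_uv * gate * _osc(t, 2 * f_mod, rng)
            cursor += block

    elif protocol.task == "oddball":
        seqs = []
        for r in range(protocol.n_runs):
            n_targ = int(rng.integers(protocol.n_targets_range[0],
                                      protocol.n_targets_range[1] + 1))
            seqs.append(gen_oddball_sequence(
                n_targ, seed=int(rng.integers(2 ** 31))))
        soa = protocol.stimulus_duration + protocol.isi
        duration = BLINK_PERIOD_S + sum(
            len(s) * soa + 5.0 for s in seqs) + 2.0
        n = int(duration * SFREQ)
        t = np.arange(n) / SFREQ
        data = _background(rng, n, effects, device)
        lat = effects.p300_latency_ms / 1e3
        width = effects.p300_width_ms / 1e3
        cursor = BLINK_PERIOD_S
        for seq in seqs:
            for label in seq:
                events.append((cursor, label))
                if label == "target":
                    jit = rng.normal(0.0, 0.010)  # trial-to-trial latency jitter
                    peak = cursor + lat + jit
                    sel = slice(int((peak - 4 * width) * SFREQ),
                                int((peak + 4 * width) * SFREQ))
                    tau = (t[sel] - peak) / width
                    bump = np.exp(-0.5 * tau ** 2)
                    data[idx["Cz"]][sel] += effects.p300_uv * bump
                    data[idx["Pz"]][sel] += 0.8 * effects.p300_uv * bump
                cursor += soa
            cursor += 5.0  # inter-run rest
    else:
        raise ValueError(f"unknown task '{protocol.task}'")

    return Recording(data=data, sfreq=SFREQ, ch_names=CHANNELS, events=events,
                     lost_mask=np.zeros(n, dtype=bool),
                     meta={"task": protocol.task, "device": device.name,
                           "seed": seed})


# ---------------------------------------------------------------------------
# artifact injection

def inject_lost_run(recording: Recording, start: int, length: int,
                    log: list | None = None) -> None:
    """Mark ``length`` consecutive samples as lost (zero-order hold values)."""
    end = min(start + length, recording.n_samples)
    recording.lost_mask[start:end] = True
    if start > 0:
        recording.data[:, start:end] = recording.data[:, start - 1:start]
    if log is not None:
        log.append({"kind": "loss", "start": int(start),
                    "length": int(end - start)})


def inject_amplitude_artifact(recording: Recording, start: int, length: int,
                              amplitude_uv: float, channel: int | None = None,
                              log: list | None = None) -> None:
    """Add a high-amplitude burst (> rejection bound).

    A single-channel event when ``channel`` is given (a popping electrode);
    otherwise all channels with a decreasing gain gradient, so the burst is
    not a pure common-mode signal that re-referencing would cancel.
    """
    end = min(start + length, recording.n_samples)
    t = np.arange(end - start) / recording.sfreq
    burst = amplitude_uv * np.sin(2 * np.pi * 4.0 * t) * np.hanning(end - start)
    if channel is None:
        gains = np.linspace(1.0, 0.3, recording.data.shape[0])
        recording.data[:, start:end] += gains[:, None] * burst[None, :]
    else:
        recording.data[channel, start:end] += burst
    if log is not None:
        log.append({"kind": "amplitude", "start": int(start),
                    "length": int(end - start), "channel": channel,
                    "amplitude_uv": float(amplitude_uv)})


def inject_ramp(recording: Recording, start: int, length: int,
                slope_uv_per_s: float, channel: int | None = None,
                log: list | None = None) -> None:
    """Replace a segment with a near-pure linear drift (electrode pop).

    Per-channel gains decrease across the montage so the ramp survives a
    common-average reference.
    """
    end = min(start + length, recording.n_samples)
    t = np.arange(end - start) / recording.sfreq
    ramp = slope_uv_per_s * (t - t.mean())
    if channel is None:
        gains = np.linspace(1.0, 0.3, recording.data.shape[0])
        recording.data[:, start:end] = gains[:, None] * ramp[None, :]
    else:
        recording.data[channel, start:end] = ramp
    if log is not None:
        log.append({"kind": "linear", "start": int(start),
                    "length": int(end - start), "channel": channel,
                    "slope_uv_per_s": float(slope_uv_per_s)})


def _blink_waveform(sfreq: float) -> np.ndarray:
    """Stereotyped 300 ms biphasic blink: dominant positive lobe with a
    shallow negative rebound."""
    n = int(0.300 * sfreq)
    t = np.linspace(0, 1, n)
    main = np.exp(-0.5 * ((t - 0.38) / 0.13) ** 2)
    rebound = -0.25 * np.exp(-0.5 * ((t - 0.75) / 0.16) ** 2)
    return main + rebound


def inject_artifacts(recording: Recording, effects: EffectSpec,
                     seed: int = 0) -> tuple[Recording, list[dict]]:
    """Add blinks, lost runs, amplitude bursts and drift ramps.

    Returns the contaminated recording and the injection log — the exact
    ground truth against which rejection rules are scored.  Loss is only
    injected if the recording's device profile enables it (the
    ``loss_enabled`` flag travels in ``recording.meta``) or if
    ``effects.loss_rate > 0`` and no profile information is present.
    """
    rng = np.random.default_rng(seed)
    rec = recording.copy()
    log: list[dict] = []
    n = rec.n_samples

    if effects.blink_rate_hz > 0:
        wave = _blink_waveform(rec.sfreq)
        n_blinks = rng.poisson(effects.blink_rate_hz * rec.duration)
        onsets = np.sort(rng.uniform(0, rec.duration - 0.4, size=n_blinks))
        topo = np.array([_BLINK_TOPO[c] for c in rec.ch_names])
        for onset in onsets:
            a = int(onset * rec.sfreq)
            amp = effects.blink_amplitude_uv * rng.uniform(0.8, 1.2)
            seg = slice(a, a + len(wave))
            rec.data[:, seg] += amp * topo[:, None] * wave[None, :len(rec.data[0, seg])]
            log.append({"kind": "blink", "start": a, "length": len(wave),
                        "amplitude_uv": float(amp)})

    loss_on = rec.meta.get("device") != "lab_grade"
    if loss_on and effects.loss_rate > 0:
        starts = np.flatnonzero(rng.random(n) < effects.loss_rate)
        for s in starts:
            if rec.lost_mask[s]:
                continue
            run = int(rng.geometric(1.0 / effects.loss_run_mean))
            inject_lost_run(rec, int(s), run, log)

    if effects.amp_artifact_rate_hz > 0:
        n_art = rng.poisson(effects.amp_artifact_rate_hz * rec.duration)
        for _ in range(n_art):
            start = int(rng.uniform(0, n - int(0.5 * rec.sfreq)))
            inject_amplitude_artifact(rec, start, int(0.5 * rec.sfreq),
                                      effects.amp_artifact_uv,
                                      channel=int(rng.integers(len(rec.data))),
                                      log=log)

    if effects.drift_rate_hz > 0:
        n_drift = rng.poisson(effects.drift_rate_hz * rec.duration)
        for _ in range(n_drift):
            start = int(rng.uniform(0, n - int(2 * rec.sfreq)))
            inject_ramp(rec, start, int(2 * rec.sfreq),
                        effects.drift_uv_per_s, log=log)

    return rec, log
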