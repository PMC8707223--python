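"""EEG preprocessing, rejection, features, statistics and power analysis.

The pipeline mirrors a standard wearable-EEG validation workflow:

1. common-average reference and zero-phase band-pass (1–30 Hz; the BCI
   preset keeps the ear reference and opens the band to 0.1–30 Hz);
2. blink removal by signal-space projection, with blinks identified on Fpz;
3. task-specific epoching;
4. four-rule artifact rejection (packet loss, amplitude, high-band PSD,
   linear drift), each epoch tagged with the first rule it trips;
5. spectral (multitaper / Welch PSD, Morlet ERSP) and time-domain (ERP)
   features;
6. condition comparison with Bonferroni-corrected t-tests or a cluster-mass
   sign-flip permutation test;
7. a trial-subsampling permutation estimate of statistical power versus the
   number of trials, summarized by n80 (trials needed for 80% power).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal, stats

from .eegsynth import Recording

__all__ = [
    "EpochSet",
    "PowerCurve",
    "ComparisonResult",
    "preprocess",
    "blink_project",
    "extract_epochs",
    "reject_epochs",
    "psd_features",
    "ersp_morlet",
    "erp_average",
    "compare_conditions",
    "power_curve",
    "feature_psd_peak",
    "feature_erp_peak",
]

VALIDATION_BAND = (1.0, 30.0)
BCI_BAND = (0.1, 30.0)
AMPLITUDE_BOUND = {"validation": 50.0, "bci": 100.0}  # µV
LOSS_RUN_LIMIT = 20        # reject if MORE than this many consecutive lost
PSD_DB_LIMIT = 60.0        # mean dB (re 1 µV²/Hz) in 20–30 Hz
PSD_BAND = (20.0, 30.0)
LINEAR_R2_LIMIT = 0.85


@dataclass
class EpochSet:
    """Trials x channels x time with rejection bookkeeping."""

    data: np.ndarray             # (n_trials, n_ch, n_times), µV
    times: np.ndarray            # seconds relative to event
    labels: np.ndarray           # condition per trial
    sfreq: float
    ch_names: tuple[str, ...]
    lost: np.ndarray             # (n_trials, n_times) bool
    rejected: np.ndarray = field(default=None)  # type: ignore[assignment]
    reject_reason: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.rejected is None:
            self.rejected = np.zeros(len(self.data), dtype=bool)
        if self.reject_reason is None:
            self.reject_reason = np.array([""] * len(self.data), dtype=object)

    @property
    def n_trials(self) -> int:
        return len(self.data)

    @property
    def accepted(self) -> np.ndarray:
        return ~self.rejected

    def accepted_data(self, label: str | None = None) -> np.ndarray:
        keep = self.accepted
        if label is not None:
            keep = keep & (self.labels == label)
        return self.data[keep]

    def channel_index(self, name: str) -> int:
        return self.ch_names.index(name)


@dataclass
class PowerCurve:
    """Proportion of significant subsampling permutations per trial count."""

    n_grid: np.ndarray
    proportion: np.ndarray
    n_perm: int
    alpha: float
    target: float = 0.8

    @property
    def n80(self) -> int | None:
        """Smallest trial count reaching the target power, if any."""
        hit = np.flatnonzero(self.proportion >= self.target)
        return int(self.n_grid[hit[0]]) if hit.size else None


@dataclass
class ComparisonResult:
    t: np.ndarray
    p: np.ndarray | None              # per-bin p (bonferroni route)
    significant: np.ndarray           # per-bin bool after correction
    method: str
    clusters: list[dict] = field(default_factory=list)


# ---------------------------------------------------------------------------
# preprocessing

def preprocess(recording: Recording, band: tuple[float, float] | None = None,
               mode: str = "validation") -> Recording:
    """Reference and band-pass filter a recording.

    ``validation``: common-average reference, then zero-phase band-pass
    1–30 Hz.  ``bci``: keeps the recording reference (ear-referenced montage)
    and band-passes 0.1–30 Hz.  Filtering is a 4th-order Butterworth applied
    forward-backward, so ERP latencies are not shifted.
    """
    if mode not in ("validation", "bci"):
        raise ValueError(f"unknown mode '{mode}'")
    if band is None:
        band = VALIDATION_BAND if mode == "validation" else BCI_BAND
    nyq = recording.sfreq / 2.0
    if not 0 < band[0] < band[1] < nyq:
        raise ValueError(f"band {band} outside (0, {nyq}) Hz")

    rec = recording.copy()
    if mode == "validation":
        if rec.data.shape[0] < 2:
            raise ValueError("common-average reference needs >= 2 channels")
        rec.data = rec.data - rec.data.mean(axis=0, keepdims=True)
    # order 5 per edge: >= 40 dB at 50 Hz for the 1-30 Hz band after the
    # forward-backward pass
    sos = signal.butter(5, band, btype="bandpass", fs=recording.sfreq,
                        output="sos")
    rec.data = signal.sosfiltfilt(sos, rec.data, axis=1)
    rec.meta = dict(rec.meta, band=band, mode=mode)
    return rec


def blink_project(recording: Recording, z_threshold: float = 3.0,
                  window_s: float = 0.200) -> Recording:
    """Remove the blink subspace by signal-space projection.

    Blinks are detected on Fpz as robust-z excursions (|z| > 3 against a
    median/MAD baseline, estimated on the free-blinking period when present);
    ±200 ms windows around detections are concatenated and the first
    principal component of that matrix — the blink topography — is projected
    out of the entire recording.
    """
    from scipy.ndimage import uniform_filter1d

    rec = recording.copy()
    # smooth over 100 ms so broadband noise does not mimic the slow blink
    fpz = uniform_filter1d(rec.channel("Fpz"), int(0.1 * rec.sfreq))
    med = np.median(fpz)
    mad = np.median(np.abs(fpz - med)) * 1.4826
    if mad <= 0:
        warnings.warn("flat Fpz channel; blink projection skipped")
        return rec
    z = (fpz - med) / mad
    # a genuine blink stays suprathreshold for most of its ~300 ms; brief
    # noise excursions above 3 robust-z do not
    min_run = int(0.150 * rec.sfreq)
    above = np.abs(z) > z_threshold
    padded = np.concatenate([[False], above, [False]])
    dd = np.diff(padded.astype(np.int8))
    runs = [(s, e) for s, e in zip(np.flatnonzero(dd == 1),
                                   np.flatnonzero(dd == -1))
            if e - s >= min_run]
    if not runs:
        warnings.warn("no blinks detected; recording returned unchanged")
        return rec

    half = int(window_s * rec.sfreq)
    peaks = [int(s + np.argmax(np.abs(z[s:e]))) for s, e in runs]
    segs = []
    for p in peaks:
        a, b = max(0, p - half), min(rec.n_samples, p + half)
        segs.append(rec.data[:, a:b])
    blink_mat = np.concatenate(segs, axis=1)
    blink_mat = blink_mat - blink_mat.mean(axis=1, keepdims=True)
    u, s, _ = np.linalg.svd(blink_mat, full_matrices=False)
    v = u[:, 0:1]                      # blink spatial topography
    rec.data = rec.data - v @ (v.T @ rec.data)
    rec.meta = dict(rec.meta, ssp_topography=v[:, 0],
                    n_blinks_detected=len(peaks))
    return rec


# ---------------------------------------------------------------------------
# epoching

_TASK_WINDOWS = {
    "eyes": (0.5, 5.0),
    "motor_move": (0.0, 4.0),
    "motor_rest": (2.0, 6.0),
    "oddball": (-0.2, 0.7),
    "bci": (0.0, 0.7),
}


def extract_epochs(recording: Recording, task: str, mode: str = "validation",
                   window: tuple[float, float] | None = None) -> EpochSet:
    """Cut task-specific epochs around event markers.

    Windows: eyes [0.5, 5] s after each state onset; motor [0, 4] s of the
    movement and [2, 6] s of the rest period; SSVEP three 50%-overlapping 5 s
    epochs per 10 s trial; oddball [−0.2, 0.7] s, baseline-corrected on
    [−0.2, 0] s (BCI preset: [0, 0.7] s, baseline = first 100 ms).  Pass
    ``window`` to override, e.g. (−6, 4) s around movement onsets for ERSP.
    """
    sf = recording.sfreq
    epochs, labels, lost = [], [], []

    def _cut(onset: float, w: tuple[float, float], label: str) -> None:
        a = int(round((onset + w[0]) * sf))
        b = a + int(round((w[1] - w[0]) * sf))
        if a < 0 or b > recording.n_samples:
            warnings.warn(f"marker at {onset:.2f} s outside recording; "
                          "epoch skipped")
            return
        epochs.append(recording.data[:, a:b])
        lost.append(recording.lost_mask[a:b])
        labels.append(label)

    if task == "eyes":
        w = window or _TASK_WINDOWS["eyes"]
        for onset, label in recording.events:
            if label in ("open", "closed"):
                _cut(onset, w, label)
        t0 = w[0]
    elif task == "motor":
        for onset, label in recording.events:
            if label == "move":
                _cut(onset, window or _TASK_WINDOWS["motor_move"], "move")
            elif label == "rest":
                _cut(onset, window or _TASK_WINDOWS["motor_rest"], "rest")
        t0 = (window or _TASK_WINDOWS["motor_move"])[0]
    elif task == "ssvep":
        w = window or (0.0, 5.0)
        length = w[1] - w[0]
        for onset, label in recording.events:
            if label.startswith("ssvep"):
                for k in range(3):             # 50% overlap over the 10 s trial
                    _cut(onset + k * length / 2, w, label)
        t0 = w[0]
    elif task in ("oddball", "bci"):
        w = window or _TASK_WINDOWS["bci" if mode == "bci" else "oddball"]
        for onset, label in recording.events:
            if label in ("target", "nontarget"):
                _cut(onset, w, label)
        t0 = w[0]
    else:
        raise ValueError(f"unknown task '{task}'")

    if not epochs:
        raise ValueError(f"no '{task}' events found in recording")
    data = np.stack(epochs)
    times = t0 + np.arange(data.shape[2]) / sf

    if task in ("oddball", "bci"):
        if mode == "bci":
            base = times < times[0] + 0.100
        else:
            base = times < 0.0
        data = data - data[:, :, base].mean(axis=2, keepdims=True)

    return EpochSet(data=data, times=times, labels=np.array(labels),
                    sfreq=sf, ch_names=recording.ch_names,
                    lost=np.stack(lost))


# ---------------------------------------------------------------------------
# rejection rules (applied in order; first hit recorded)

def _max_lost_run(mask: np.ndarray) -> int:
    if not mask.any():
        return 0
    padded = np.concatenate([[False], mask, [False]])
    d = np.diff(padded.astype(np.int8))
    return int(np.max(np.flatnonzero(d == -1) - np.flatnonzero(d == 1)))


def rule_loss(epoch: np.ndarray, lost: np.ndarray, sfreq: float) -> bool:
    """Reject if strictly more than 20 consecutive samples were lost."""
    return _max_lost_run(lost) > LOSS_RUN_LIMIT


def rule_amplitude(epoch: np.ndarray, lost: np.ndarray, sfreq: float,
                   bound: float = 50.0) -> bool:
    """Reject if any sample lies outside the ±bound µV range."""
    return bool(np.max(np.abs(epoch)) > bound)


def rule_psd(epoch: np.ndarray, lost: np.ndarray, sfreq: float) -> bool:
    """Reject if mean multitaper PSD in 20–30 Hz exceeds 60 dB re 1 µV²/Hz
    on any channel."""
    from mne.time_frequency import psd_array_multitaper

    psd, freqs = psd_array_multitaper(epoch, sfreq, fmin=1.0, fmax=30.0,
                                      bandwidth=4.0, adaptive=False,
                                      verbose="error")
    band = (freqs >= PSD_BAND[0]) & (freqs <= PSD_BAND[1])
    db = 10.0 * np.log10(np.maximum(psd[:, band], 1e-30))
    return bool(np.max(db.mean(axis=1)) > PSD_DB_LIMIT)


def rule_linear(epoch: np.ndarray, lost: np.ndarray, sfreq: float) -> bool:
    """Reject if any channel is well fit by a straight line (r² > 0.85).
    Constant channels define r² = 0."""
    n = epoch.shape[1]
    t = np.arange(n, dtype=float)
    t = t - t.mean()
    x = epoch - epoch.mean(axis=1, keepdims=True)
    denom = np.sqrt(np.sum(t ** 2) * np.sum(x ** 2, axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (x @ t) / np.maximum(denom, 1e-30), 0.0)
    return bool(np.max(r ** 2) > LINEAR_R2_LIMIT)


def reject_epochs(epochs: EpochSet, mode: str = "validation"
                  ) -> tuple[EpochSet, dict[str, int]]:
    """Apply the rejection rules in order; report per-rule counts.

    Validation preset: loss, amplitude (±50 µV), PSD, linear.  BCI preset:
    loss and amplitude (±100 µV) only.  Each rejected epoch records the first
    rule that triggered.  The returned report also lists the flagged epochs
    (the dry-run stand-in for manual review of a semi-automatic procedure).
    """
    bound = AMPLITUDE_BOUND[mode]
    rules = [("loss", rule_loss),
             ("amplitude", lambda e, l, s: rule_amplitude(e, l, s, bound))]
    if mode == "validation":
        rules += [("psd", rule_psd), ("linear", rule_linear)]

    counts = {name: 0 for name, _ in rules}
    flagged: list[int] = []
    for i in range(epochs.n_trials):
        for name, fn in rules:
            if fn(epochs.data[i], epochs.lost[i], epochs.sfreq):
                epochs.rejected[i] = True
                epochs.reject_reason[i] = name
                counts[name] += 1
                flagged.append(i)
                break
    counts["flagged_epochs"] = flagged  # type: ignore[assignment]
    return epochs, counts


# ---------------------------------------------------------------------------
# features

def psd_features(epochs: EpochSet, method: str = "multitaper",
                 fmin: float = 1.0, fmax: float = 30.0
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Per-epoch PSD in µV²/Hz.

    ``multitaper``: DPSS tapers with 2 Hz half-bandwidth over [fmin, fmax].
    ``welch``: Hann window, 2000-sample segments, 1000-sample overlap,
    5000-point FFT (0.1 Hz grid at 500 Hz).

    Returns (freqs, psd) with psd shaped (n_trials, n_ch, n_freqs).
    """
    if method == "multitaper":
        from mne.time_frequency import psd_array_multitaper

        psd, freqs = psd_array_multitaper(
            epochs.data, epochs.sfreq, fmin=fmin, fmax=fmax,
            bandwidth=4.0, adaptive=False, verbose="error")
        return freqs, psd
    if method == "welch":
        nperseg = 2000
        if epochs.data.shape[2] < nperseg:
            raise ValueError(
                f"epochs of {epochs.data.shape[2]} samples are shorter than "
                f"the {nperseg}-sample Welch segment")
        freqs, psd = signal.welch(epochs.data, fs=epochs.sfreq,
                                  window="hann", nperseg=nperseg,
                                  noverlap=1000, nfft=5000, axis=2)
        keep = (freqs >= fmin) & (freqs <= fmax)
        return freqs[keep], psd[..., keep]
    raise ValueError(f"unknown PSD method '{method}'")


def ersp_morlet(epochs: EpochSet,
                baseline_window: tuple[float, float] = (-6.0, 0.0),
                label: str | None = None
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Event-related spectral perturbation in dB.

    Morlet wavelets at 1..30 Hz with cycle counts 1..30 matched index-wise;
    power is averaged across accepted trials and converted to dB against the
    mean pre-event baseline power per channel and frequency.

    Returns (freqs, times, ersp) with ersp shaped (n_ch, n_freqs, n_times).
    """
    lo, hi = baseline_window
    if lo < epochs.times[0] - 1e-9 or hi > epochs.times[-1] + 1e-9:
        raise ValueError(
            f"baseline {baseline_window} outside epoch "
            f"[{epochs.times[0]:.2f}, {epochs.times[-1]:.2f}] s")
    from mne.time_frequency import tfr_array_morlet

    freqs = np.arange(1.0, 31.0)
    n_cycles = np.arange(1.0, 31.0)
    data = epochs.accepted_data(label)
    if len(data) == 0:
        raise ValueError("no accepted trials for ERSP")
    power = tfr_array_morlet(data, epochs.sfreq, freqs=freqs,
                             n_cycles=n_cycles, output="power",
                             verbose="error")
    mean_power = power.mean(axis=0)  # (n_ch, n_f, n_t)
    base = (epochs.times >= lo) & (epochs.times <= hi)
    baseline = mean_power[:, :, base].mean(axis=2, keepdims=True)
    ersp = 10.0 * np.log10(mean_power / np.maximum(baseline, 1e-30))
    return freqs, epochs.times, ersp


def erp_average(epochs: EpochSet,
                peak_window: tuple[float, float] | None = None
                ) -> dict[str, dict]:
    """Per-condition mean waveform ± sd over accepted trials.

    If ``peak_window`` is given, the maximum of the mean waveform inside it
    is reported per channel as (amplitude, latency).
    """
    out: dict[str, dict] = {}
    for label in np.unique(epochs.labels):
        data = epochs.accepted_data(label)
        if len(data) == 0:
            raise ValueError(f"no accepted trials for condition '{label}'")
        mean = data.mean(axis=0)
        sd = data.std(axis=0, ddof=1) if len(data) > 1 else np.zeros_like(mean)
        entry = {"mean": mean, "sd": sd, "n": len(data)}
        if peak_window is not None:
            sel = ((epochs.times >= peak_window[0])
                   & (epochs.times <= peak_window[1]))
            seg = mean[:, sel]
            k = np.argmax(seg, axis=1)
            entry["peak_amplitude"] = seg[np.arange(len(seg)), k]
            entry["peak_latency"] = epochs.times[sel][k]
        out[str(label)] = entry
    return out


# ---------------------------------------------------------------------------
# statistics

def compare_conditions(features_a: np.ndarray, features_b: np.ndarray,
                       correction: str = "bonferroni", alpha: float = 0.05,
                       n_perm: int = 1000, seed: int = 0
                       ) -> ComparisonResult:
    """Bin-wise comparison of two condition feature matrices (trials x bins).

    ``bonferroni``: independent two-sample t-test per bin, significant at
    alpha / n_bins.  ``cluster``: dependent-sample t per bin on paired
    differences, clusters of contiguous supra-threshold bins (two-sided
    threshold at the alpha t-quantile), cluster mass = sum of t inside; the
    null is the distribution of the maximal |mass| over sign-flip
    permutations of the paired differences (exhaustive when 2**n <= n_perm),
    and each cluster's corrected p is the proportion of permutation maxima at
    least as large as its observed |mass|.
    """
    a = np.atleast_2d(np.asarray(features_a, dtype=float))
    b = np.atleast_2d(np.asarray(features_b, dtype=float))
    if a.shape[1] != b.shape[1]:
        raise ValueError("feature grids do not match")
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 trials per condition")

    if correction == "bonferroni":
        t, p = stats.ttest_ind(a, b, axis=0)
        sig = p < alpha / a.shape[1]
        return ComparisonResult(t=t, p=p, significant=sig,
                                method="bonferroni")

    if correction != "cluster":
        raise ValueError(f"unknown correction '{correction}'")

    n = min(len(a), len(b))
    d = a[:n] - b[:n]
    m = d.shape[1]
    thr = stats.t.ppf(1.0 - alpha / 2.0, df=n - 1)

    def _tstat(x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=0)
        se = x.std(axis=0, ddof=1) / np.sqrt(len(x))
        return mu / np.maximum(se, 1e-30)

    def _clusters(t: np.ndarray) -> list[tuple[int, int, float]]:
        found = []
        for sign in (1.0, -1.0):
            above = sign * t > thr
            padded = np.concatenate([[False], above, [False]])
            dd = np.diff(padded.astype(np.int8))
            for s, e in zip(np.flatnonzero(dd == 1), np.flatnonzero(dd == -1)):
                found.append((int(s), int(e), float(t[s:e].sum())))
        return found

    t_obs = _tstat(d)
    obs_clusters = _clusters(t_obs)

    if 2 ** n <= n_perm:
        flips = ((np.arange(2 ** n)[:, None] >> np.arange(n)) & 1) * 2 - 1
    else:
        rng = np.random.default_rng(seed)
        flips = rng.choice([-1, 1], size=(n_perm, n))
    null_max = np.empty(len(flips))
    for i, fl in enumerate(flips):
        masses = [abs(mass) for _, _, mass in _clusters(_tstat(d * fl[:, None]))]
        null_max[i] = max(masses) if masses else 0.0

    clusters = []
    sig = np.zeros(m, dtype=bool)
    for s, e, mass in obs_clusters:
        p_c = float(np.mean(null_max >= abs(mass)))
        clusters.append({"start": s, "end": e, "mass": mass, "p": p_c})
        if p_c < alpha:
            sig[s:e] = True
    return ComparisonResult(t=t_obs, p=None, significant=sig,
                            method="cluster", clusters=clusters)


def power_curve(trials_a: np.ndarray, trials_b: np.ndarray,
                feature_fn, n_grid, n_perm: int = 1000,
                alpha: float = 0.05, target: float = 0.8,
                seed: int = 0) -> PowerCurve:
    """Statistical power versus number of trials by subsampling permutation.

    ``feature_fn`` maps one trial (channels x time) to a scalar; it is
    evaluated once per trial.  For each n in ``n_grid``, ``n_perm`` random
    subsamples of n trials per condition (without replacement) are drawn, the
    two feature samples compared with a two-sided independent t-test, and the
    proportion of draws with p < alpha recorded.
    """
    feats_a = np.array([feature_fn(tr) for tr in trials_a], dtype=float)
    feats_b = np.array([feature_fn(tr) for tr in trials_b], dtype=float)
    n_max = min(len(feats_a), len(feats_b))
    n_grid = np.asarray(sorted(int(n) for n in n_grid))
    if n_grid[-1] > n_max:
        warnings.warn(f"n_grid truncated at the {n_max} available trials")
        n_grid = n_grid[n_grid <= n_max]
    if n_grid.size == 0 or n_grid[0] < 2:
        raise ValueError("n_grid must contain counts >= 2 within the data")

    rng = np.random.default_rng(seed)
    proportion = np.empty(len(n_grid))
    for gi, n in enumerate(n_grid):
        # vectorized subsampling: first n of a random permutation per draw
        idx_a = np.argpartition(rng.random((n_perm, len(feats_a))), n - 1,
                                axis=1)[:, :n]
        idx_b = np.argpartition(rng.random((n_perm, len(feats_b))), n - 1,
                                axis=1)[:, :n]
        xa, xb = feats_a[idx_a], feats_b[idx_b]
        va = xa.var(axis=1, ddof=1)
        vb = xb.var(axis=1, ddof=1)
        sp = np.sqrt((va + vb) / 2.0) * np.sqrt(2.0 / n)
        t = (xa.mean(axis=1) - xb.mean(axis=1)) / np.maximum(sp, 1e-30)
        p = 2.0 * stats.t.sf(np.abs(t), df=2 * n - 2)
        proportion[gi] = np.mean(p < alpha)

    return PowerCurve(n_grid=n_grid, proportion=proportion, n_perm=n_perm,
                      alpha=alpha, target=target)


# ---------------------------------------------------------------------------
# scalar per-trial features used by the power analysis

def feature_psd_peak(sfreq: float, ch_idx: int, fmin: float, fmax: float):
    """Peak Welch-PSD amplitude of one channel inside [fmin, fmax] Hz."""
    def fn(trial: np.ndarray) -> float:
        x = trial[ch_idx]
        nper = min(2000, len(x))
        freqs, psd = signal.welch(x, fs=sfreq, window="hann", nperseg=nper,
                                  noverlap=nper // 2, nfft=5000)
        band = (freqs >= fmin) & (freqs <= fmax)
        return float(psd[band].max())
    return fn


def feature_erp_peak(times: np.ndarray, ch_idx: int,
                     tmin: float, tmax: float):
    """Peak amplitude of one channel inside the [tmin, tmax] s window."""
    sel = (times >= tmin) & (times <= tmax)

    def fn(trial: np.ndarray) -> float:
        return float(trial[ch_idx, sel].max())
    return fn
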