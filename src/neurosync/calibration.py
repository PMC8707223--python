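"""Perturbation-based inter-stream offset calibration.

Clock synchronization cannot see wireless transport delays, so residual
inter-stream offsets remain after remapping.  When every device rides the
same rigid structure, a mechanical perturbation (random shaking, sharp taps)
appears in all accelerometer streams at the same physical instant; the lag
of the cross-correlation peak between any two magnitude traces during those
perturbations *is* the relative transport delay.  Averaging per-session lags
across cold restarts yields the offset matrix used to compensate streams.

Sign convention: a positive offset (i, j) means stream j's content trails
stream i's, i.e. j's copy of the perturbation arrives later.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .streamsim import SimulatedStream

__all__ = [
    "CalibrationError",
    "OffsetMatrix",
    "magnitude",
    "resample_common",
    "find_perturbation_chunks",
    "estimate_pairwise_lag",
    "build_offset_matrix",
    "compensate",
]

TARGET_RATE = 1000.0  # Hz, shared grid for correlation
MAX_LAG_S = 0.500     # +/- search window


class CalibrationError(RuntimeError):
    pass


@dataclass
class OffsetMatrix:
    """Pairwise inter-stream content offsets, averaged across sessions.

    ``mean_ms[i, j]`` is the mean lag of device j behind device i in ms;
    ``samples[i, j]`` the same offset expressed in device j's samples,
    ``round(mean_ms[i, j] * rate_j / 1000)``.
    """

    devices: list[str]
    mean_ms: np.ndarray
    sd_ms: np.ndarray
    samples: np.ndarray
    rates: dict[str, float]

    def to_frame(self):
        import pandas as pd

        cells = np.empty((len(self.devices), len(self.devices)), dtype=object)
        for i in range(len(self.devices)):
            for j in range(len(self.devices)):
                cells[i, j] = (f"{self.mean_ms[i, j]:.0f} ± "
                               f"{self.sd_ms[i, j]:.0f} "
                               f"[{abs(self.samples[i, j])}]")
        return pd.DataFrame(cells, index=self.devices, columns=self.devices)

    def offset_ms(self, ref: str, device: str) -> float:
        return float(self.mean_ms[self.devices.index(ref),
                                  self.devices.index(device)])


def magnitude(samples: np.ndarray) -> np.ndarray:
    """Mean-removed Euclidean norm of a 3-axis accelerometer stream.

    Rotation-invariant, so devices mounted in arbitrary orientations see the
    same perturbation waveform.  Single-channel input is accepted (absolute
    value); anything else is rejected.
    """
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    if samples.shape[0] not in (1, 3):
        raise ValueError(
            f"expected a 1- or 3-axis stream, got {samples.shape[0]} channels")
    mag = np.sqrt(np.sum(samples ** 2, axis=0))
    return mag - np.nanmean(mag)


def resample_common(streams: list[SimulatedStream],
                    target_rate: float = TARGET_RATE
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Linearly interpolate all magnitude traces onto one shared grid.

    Returns ``(grid, traces, valid)`` where ``grid`` is the 1 kHz timeline
    spanning the intersection of supports, ``traces`` is (n_streams, n) and
    ``valid`` a boolean mask, False where a stream's nearest source samples
    were lost (those regions are excluded from correlation, not invented by
    interpolation).
    """
    if not streams:
        raise CalibrationError("no streams to resample")
    t0 = max(float(np.nanmin(_shared_t(s))) for s in streams)
    t1 = min(float(np.nanmax(_shared_t(s))) for s in streams)
    if t1 <= t0:
        raise CalibrationError("streams have no temporal overlap")

    n = int(np.floor((t1 - t0) * target_rate)) + 1
    grid = t0 + np.arange(n) / target_rate
    traces = np.zeros((len(streams), n))
    valid = np.ones((len(streams), n), dtype=bool)
    for k, s in enumerate(streams):
        ts = _shared_t(s)
        mag = magnitude(s.samples)
        ok = ~np.asarray(s.lost_mask, dtype=bool) & np.isfinite(mag)
        if ok.sum() < 2:
            raise CalibrationError(
                f"stream '{s.device.name}' has fewer than 2 usable samples")
        traces[k] = np.interp(grid, ts[ok], mag[ok])
        if (~ok).any():
            # a grid point is invalid if its enclosing source interval
            # touches a lost sample
            bad_t = ts[~ok]
            half = 1.0 / s.device.nominal_rate
            idx = np.searchsorted(grid, np.column_stack(
                [bad_t - half, bad_t + half]))
            for a, b in idx:
                valid[k, a:b] = False
    return grid, traces, valid


def _shared_t(s: SimulatedStream) -> np.ndarray:
    if s.shared_timestamps is None:
        raise CalibrationError(
            f"stream '{s.device.name}' must be remapped before calibration")
    return np.asarray(s.shared_timestamps, dtype=float)


def find_perturbation_chunks(trace: np.ndarray,
                             rate: float = TARGET_RATE,
                             *, window_s: float = 0.100,
                             mad_factor: float = 10.0,
                             merge_gap_s: float = 0.200,
                             min_len_s: float = 0.100
                             ) -> list[tuple[int, int]]:
    """Locate perturbation windows in a magnitude trace.

    A 100 ms moving RMS is thresholded at ``median + 10 * MAD`` of the whole
    RMS trace; nearby windows (< 200 ms apart) are merged and windows shorter
    than 100 ms dropped.  Returns (start, end) sample indices.
    """
    from scipy.ndimage import uniform_filter1d

    trace = np.asarray(trace, dtype=float)
    w = max(int(round(window_s * rate)), 1)
    mov_rms = np.sqrt(uniform_filter1d(trace ** 2, size=w, mode="nearest"))
    med = np.median(mov_rms)
    mad = np.median(np.abs(mov_rms - med))
    threshold = med + mad_factor * max(mad, 1e-30)

    above = mov_rms > threshold
    if not above.any():
        raise CalibrationError(
            "no perturbation found; apply a stronger mechanical stimulus")
    padded = np.concatenate([[False], above, [False]])
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)

    merged: list[list[int]] = []
    gap = int(round(merge_gap_s * rate))
    for s, e in zip(starts, ends):
        if merged and s - merged[-1][1] < gap:
            merged[-1][1] = e
        else:
            merged.append([int(s), int(e)])
    min_len = int(round(min_len_s * rate))
    chunks = [(s, e) for s, e in merged if e - s >= min_len]
    if not chunks:
        raise CalibrationError(
            "perturbations too brief; apply a longer mechanical stimulus")
    return chunks


def estimate_pairwise_lag(ref: np.ndarray, other: np.ndarray,
                          chunks: list[tuple[int, int]],
                          rate: float = TARGET_RATE,
                          *, max_lag_s: float = MAX_LAG_S,
                          valid_ref: np.ndarray | None = None,
                          valid_other: np.ndarray | None = None,
                          combine: str = "mean"
                          ) -> tuple[float, list[float]]:
    """Cross-correlation lag of ``other`` behind ``ref``, in ms.

    For each perturbation chunk, the normalized cross-correlation between the
    ref segment and the other trace is scanned over integer sample shifts in
    ``[-max_lag, +max_lag]`` (1 ms steps at the 1 kHz grid); the argmax is
    that chunk's lag.  Positive lag means ``other`` trails ``ref``.  The
    returned scalar is the mean (or median) of per-chunk lags.

    Lost-sample regions (``valid_*`` False) are zeroed, i.e. masked out of
    the correlation sums rather than interpolated.
    """
    ref = np.asarray(ref, dtype=float).copy()
    other = np.asarray(other, dtype=float).copy()
    if valid_ref is not None:
        ref[~np.asarray(valid_ref, dtype=bool)] = 0.0
    if valid_other is not None:
        other[~np.asarray(valid_other, dtype=bool)] = 0.0

    w = int(round(max_lag_s * rate))
    n = len(ref)
    per_chunk: list[float] = []
    for a, b in chunks:
        if (b - a) < 2 * w:
            warnings.warn(
                "perturbation chunk shorter than twice the max lag; skipped")
            continue
        seg = ref[a:b] - ref[a:b].mean()
        lo, hi = a - w, b + w
        pad_lo, pad_hi = max(0, -lo), max(0, hi - n)
        ext = np.pad(other[max(0, lo):min(n, hi)], (pad_lo, pad_hi))
        ext = ext - ext.mean()
        cc = np.correlate(ext, seg, mode="valid")  # length 2w + 1
        # sliding norm of the other-trace window for normalized correlation
        csum2 = np.concatenate([[0.0], np.cumsum(ext ** 2)])
        win_energy = csum2[len(seg):] - csum2[:-len(seg)]
        denom = np.sqrt(win_energy * np.sum(seg ** 2))
        ncc = np.where(denom > 0, cc / np.maximum(denom, 1e-30), -np.inf)
        k = int(np.argmax(ncc)) - w
        per_chunk.append(k / rate * 1e3)

    if not per_chunk:
        raise CalibrationError("all chunks were too short for lag estimation")
    if combine == "median":
        lag = float(np.median(per_chunk))
    else:
        lag = float(np.mean(per_chunk))
    return lag, per_chunk


def build_offset_matrix(session_lags: list[np.ndarray], devices: list[str],
                        rates: dict[str, float]) -> OffsetMatrix:
    """Average per-session pairwise lag matrices into an offset matrix.

    ``session_lags`` holds one (d, d) lag matrix (ms) per session.  Mean and
    sample standard deviation are taken across sessions, the mean matrix is
    antisymmetrized as (M − Mᵀ)/2, and the samples matrix converts each mean
    offset into the receiving device's sample counts.
    """
    stack = np.stack([np.asarray(m, dtype=float) for m in session_lags])
    if stack.shape[0] == 1:
        warnings.warn("single session: offset sd reported as 0")
        sd = np.zeros_like(stack[0])
    else:
        sd = stack.std(axis=0, ddof=1)
    mean = stack.mean(axis=0)
    mean = 0.5 * (mean - mean.T)
    np.fill_diagonal(mean, 0.0)
    np.fill_diagonal(sd, 0.0)

    rate_j = np.array([rates[d] for d in devices])
    samples = np.round(mean * rate_j[None, :] / 1000.0).astype(int)
    return OffsetMatrix(devices=list(devices), mean_ms=mean, sd_ms=sd,
                        samples=samples, rates=dict(rates))


def compensate(streams: list[SimulatedStream], matrix: OffsetMatrix,
               ref_device: str) -> list[SimulatedStream]:
    """Shift each stream's shared timeline so content aligns with the
    reference device: timestamps minus mean offset(ref, device)."""
    if ref_device not in matrix.devices:
        raise CalibrationError(f"reference '{ref_device}' not in matrix")
    out = []
    for s in streams:
        if s.device.name not in matrix.devices:
            raise CalibrationError(
                f"device '{s.device.name}' missing from offset matrix")
        shift_ms = matrix.offset_ms(ref_device, s.device.name)
        shifted = SimulatedStream(
            device=s.device, samples=s.samples,
            raw_timestamps=s.raw_timestamps, lost_mask=s.lost_mask,
            clock_offset_history=s.clock_offset_history, clock=s.clock,
            shared_timestamps=_shared_t(s) - shift_ms / 1e3,
            meta=dict(s.meta, compensation_ms=float(shift_ms),
                      compensation_ref=ref_device))
        out.append(shifted)
    return out
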