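"""Clock correction, timestamp remapping and jitter removal.

The recorder periodically measures each device's momentary clock offset
against its own clock.  A linear model fitted to that offset history captures
boot offset (intercept) and rate error (slope); subtracting the fitted offset
from the raw timestamps remaps every stream onto the recorder's shared
timeline.  The fit is Theil–Sen, so a few corrupt handshake measurements do
not bend the line.

Transport latency is deliberately left untouched here: it is invisible to
clock synchronization and is estimated by the perturbation calibration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .streamsim import SimulatedStream

__all__ = [
    "ClockCorrection",
    "UnsynchronizableError",
    "fit_clock_correction",
    "remap_timestamps",
    "dejitter",
    "detect_lost_runs",
]


class UnsynchronizableError(RuntimeError):
    """Stream lacks enough clock-offset measurements to be remapped."""


@dataclass(frozen=True)
class ClockCorrection:
    """Affine offset model: corrected_offset(t) = intercept + slope * t."""

    intercept: float  # seconds
    slope: float      # dimensionless

    def offset_at(self, t):
        return self.intercept + self.slope * np.asarray(t, dtype=float)

    def apply(self, raw_t):
        """Map raw device timestamps into shared time."""
        raw_t = np.asarray(raw_t, dtype=float)
        return raw_t - self.offset_at(raw_t)

    def inverse(self) -> "ClockCorrection":
        """Exact algebraic inverse: applying it to shared time restores raw."""
        denom = 1.0 - self.slope
        return ClockCorrection(intercept=-self.intercept / denom,
                               slope=-self.slope / denom)


def fit_clock_correction(history: np.ndarray) -> ClockCorrection:
    """Fit the clock-offset history with a robust line.

    Parameters
    ----------
    history : (m, 2) array
        Columns (measurement_time, measured_offset), seconds.  At least two
        measurements are required.

    Notes
    -----
    Theil–Sen (median of pairwise slopes) with its companion intercept keeps
    the fit stable when up to ~29% of measurements are gross outliers, e.g.
    handshake transients at stream startup.  With exactly two points it
    degenerates to the straight line through them.
    """
    history = np.asarray(history, dtype=float)
    if history.ndim != 2 or history.shape[1] != 2 or history.shape[0] < 2:
        raise UnsynchronizableError(
            "need at least 2 clock-offset measurements to synchronize")
    t, off = history[:, 0], history[:, 1]
    if np.ptp(t) == 0:
        raise UnsynchronizableError("offset measurements share one timestamp")
    from scipy.stats import theilslopes

    slope, intercept, _, _ = theilslopes(off, t)
    return ClockCorrection(intercept=float(intercept), slope=float(slope))


def remap_timestamps(stream: SimulatedStream,
                     correction: ClockCorrection) -> SimulatedStream:
    """Return a copy of the stream with shared-time timestamps attached."""
    shared = correction.apply(stream.raw_timestamps)
    out = _replace_stream(stream)
    out.shared_timestamps = shared
    out.meta = dict(stream.meta, clock_correction=(correction.intercept,
                                                   correction.slope))
    return out


def _replace_stream(stream: SimulatedStream) -> SimulatedStream:
    return SimulatedStream(
        device=stream.device, samples=stream.samples,
        raw_timestamps=stream.raw_timestamps, lost_mask=stream.lost_mask,
        clock_offset_history=stream.clock_offset_history, clock=stream.clock,
        shared_timestamps=stream.shared_timestamps, meta=dict(stream.meta))


def dejitter(stream: SimulatedStream) -> SimulatedStream:
    """Replace noisy timestamps with a per-segment least-squares grid.

    The timeline is split wherever the inter-sample gap exceeds
    ``max(2 / nominal_rate, 10 ms)`` (a dropout); within each contiguous
    segment the timestamps are replaced by an ordinary least-squares line in
    sample index, which is the maximum-likelihood equispaced grid under
    Gaussian timestamp noise.  The residual standard deviation per segment is
    reported in ``meta['dejitter_residual_sd']``.
    """
    ts = (stream.shared_timestamps if stream.shared_timestamps is not None
          else stream.raw_timestamps)
    ts = np.asarray(ts, dtype=float)
    n = len(ts)
    threshold = max(2.0 / stream.device.nominal_rate, 0.010)
    gaps = np.diff(ts)
    breaks = np.flatnonzero(gaps > threshold) + 1
    bounds = np.concatenate([[0], breaks, [n]])

    out_ts = ts.copy()
    residual_sds = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        idx = np.arange(b - a, dtype=float)
        if b - a >= 2:
            slope, intercept = np.polyfit(idx, ts[a:b], 1)
            fitted = intercept + slope * idx
            residual_sds.append(float(np.std(ts[a:b] - fitted)))
            out_ts[a:b] = fitted
        else:
            residual_sds.append(0.0)

    out = _replace_stream(stream)
    out.shared_timestamps = out_ts
    out.meta = dict(stream.meta, dejitter_residual_sd=residual_sds,
                    n_segments=len(bounds) - 1)
    return out


def detect_lost_runs(stream: SimulatedStream) -> list[tuple[int, int]]:
    """Maximal runs of consecutive lost samples as (start_index, length)."""
    mask = np.asarray(stream.lost_mask, dtype=bool)
    if mask.size == 0 or not mask.any():
        return []
    padded = np.concatenate([[False], mask, [False]])
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return [(int(s), int(e - s)) for s, e in zip(starts, ends)]
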