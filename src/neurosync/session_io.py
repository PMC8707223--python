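"""Session container I/O.

A recorded session is a set of heterogeneous timestamped streams plus, for
simulated sessions, exact ground truth (clock models, drawn transport
latencies, the reference motion trace).  Everything lives in a single HDF5
file: one group per stream carrying samples, raw timestamps, lost mask and
the clock-offset measurement history, plus a ``ground_truth`` sidecar group
that third-party files simply omit.
"""

from __future__ import annotations

import numpy as np

from .streamsim import ClockModel, DeviceSpec, SimSession, SimulatedStream

__all__ = ["write_session", "read_session", "SessionFormatError"]

_FORMAT_VERSION = 1


class SessionFormatError(ValueError):
    """Raised when a session file cannot be parsed; names the stream."""


def write_session(session: SimSession, path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = _FORMAT_VERSION
        f.attrs["duration"] = session.duration
        f.attrs["seed"] = session.seed
        g_streams = f.create_group("streams")
        for i, s in enumerate(session.streams):
            g = g_streams.create_group(f"{i:03d}_{s.device.name}")
            g.attrs["name"] = s.device.name
            g.attrs["nominal_rate"] = s.device.nominal_rate
            g.attrs["channel_labels"] = list(s.device.channel_labels)
            g.attrs["loss_rate"] = s.device.loss_rate
            g.attrs["loss_run_mean"] = s.device.loss_run_mean
            g.create_dataset("samples", data=s.samples)
            g.create_dataset("raw_timestamps", data=s.raw_timestamps)
            g.create_dataset("lost_mask", data=s.lost_mask)
            g.create_dataset("clock_offset_history", data=s.clock_offset_history)
            if s.shared_timestamps is not None:
                g.create_dataset("shared_timestamps", data=s.shared_timestamps)

        gt = f.create_group("ground_truth")
        names = list(session.ground_truth_latencies)
        gt.attrs["devices"] = names
        gt.create_dataset(
            "transport_latencies",
            data=np.array([session.ground_truth_latencies[n] for n in names]))
        g_clocks = gt.create_group("clocks")
        for name, c in session.clocks.items():
            gc = g_clocks.create_group(name)
            for attr in ("offset0", "drift", "jitter_sd",
                         "transport_latency", "transport_latency_sd"):
                gc.attrs[attr] = getattr(c, attr)
        if session.motion is not None:
            gt.create_dataset("motion", data=session.motion)


def read_session(path) -> SimSession:
    import h5py

    with h5py.File(path, "r") as f:
        if "streams" not in f:
            raise SessionFormatError(f"{path}: no 'streams' group")
        streams: list[SimulatedStream] = []
        for key in sorted(f["streams"]):
            g = f["streams"][key]
            try:
                device = DeviceSpec(
                    name=str(g.attrs["name"]),
                    nominal_rate=float(g.attrs["nominal_rate"]),
                    channel_labels=tuple(str(c) for c in g.attrs["channel_labels"]),
                    loss_rate=float(g.attrs.get("loss_rate", 0.0)),
                    loss_run_mean=float(g.attrs.get("loss_run_mean", 5.0)),
                )
                history = (np.asarray(g["clock_offset_history"])
                           if "clock_offset_history" in g
                           else np.empty((0, 2)))
                stream = SimulatedStream(
                    device=device,
                    samples=np.asarray(g["samples"]),
                    raw_timestamps=np.asarray(g["raw_timestamps"]),
                    lost_mask=np.asarray(g["lost_mask"], dtype=bool),
                    clock_offset_history=history,
                    shared_timestamps=(np.asarray(g["shared_timestamps"])
                                       if "shared_timestamps" in g else None),
                )
            except KeyError as exc:
                raise SessionFormatError(
                    f"{path}: stream '{key}' is missing {exc}") from exc
            streams.append(stream)

        latencies: dict[str, float] = {}
        clocks: dict[str, ClockModel] = {}
        motion = None
        if "ground_truth" in f:
            gt = f["ground_truth"]
            names = [str(n) for n in gt.attrs["devices"]]
            lat = np.asarray(gt["transport_latencies"])
            latencies = dict(zip(names, lat.tolist()))
            for name in gt["clocks"]:
                gc = gt["clocks"][name]
                clocks[name] = ClockModel(
                    offset0=float(gc.attrs["offset0"]),
                    drift=float(gc.attrs["drift"]),
                    jitter_sd=float(gc.attrs["jitter_sd"]),
                    transport_latency=float(gc.attrs["transport_latency"]),
                    transport_latency_sd=float(gc.attrs["transport_latency_sd"]),
                )
            if "motion" in gt:
                motion = np.asarray(gt["motion"])
            for s in streams:
                if s.device.name in clocks:
                    s.clock = clocks[s.device.name]

        return SimSession(
            streams=streams,
            duration=float(f.attrs["duration"]),
            seed=int(f.attrs.get("seed", -1)),
            ground_truth_latencies=latencies,
            clocks=clocks,
            motion=motion,
        )
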