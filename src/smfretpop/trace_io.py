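"""Trace containers and file formats.

Two interchange formats are supported:

* a long-format CSV with header ``trace_id,frame,time_s,donor,acceptor``
  (frames 0-based, UTF-8, '.' decimal), trivially inspectable; and
* a fully specified little-endian binary container in the spirit of the
  ``.traces`` files produced by common TIRF acquisition scripts:
  ``int32 n_frames; int32 n_traces; float32 dt`` followed, per trace, by
  ``n_frames`` int16 donor values and ``n_frames`` int16 acceptor values.
  The layout used by any particular acquisition setup is not standardized;
  this dialect is a documented stand-in.

Intensities are stored as provided; no rescaling is performed on I/O.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, CorruptFileError

#: tolerance on frame-interval uniformity, seconds
DT_TOL = 1e-6

CSV_COLUMNS = ["trace_id", "frame", "time_s", "donor", "acceptor"]


@dataclass
class Trace:
    """One molecule's donor/acceptor intensity time series.

    Attributes
    ----------
    trace_id : str
        Unique identifier within a set.
    time_s, donor, acceptor : ndarray
        Equal-length per-frame timestamp (s) and channel intensities (counts).
    meta : dict
        Free-form metadata (condition label, replicate id, ...).
    """

    trace_id: str
    time_s: np.ndarray
    donor: np.ndarray
    acceptor: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.donor = np.asarray(self.donor, dtype=float)
        self.acceptor = np.asarray(self.acceptor, dtype=float)
        n = len(self.time_s)
        if len(self.donor) != n or len(self.acceptor) != n:
            raise FormatError(
                f"trace {self.trace_id!r}: ragged channel lengths "
                f"(time {n}, donor {len(self.donor)}, acceptor {len(self.acceptor)})"
            )
        if n >= 2:
            steps = np.diff(self.time_s)
            if np.any(steps <= 0):
                raise FormatError(f"trace {self.trace_id!r}: time_s not strictly increasing")
            if np.ptp(steps) > DT_TOL:
                raise FormatError(f"trace {self.trace_id!r}: non-constant frame interval")

    @property
    def n_frames(self) -> int:
        return len(self.time_s)

    @property
    def dt(self) -> float:
        if self.n_frames < 2:
            return float("nan")
        return float(self.time_s[1] - self.time_s[0])

    @property
    def total(self) -> np.ndarray:
        """Summed donor + acceptor intensity per frame."""
        return self.donor + self.acceptor


@dataclass
class TraceSet:
    """Ordered collection of traces recorded at a uniform frame interval."""

    traces: list[Trace]
    dt: float
    condition: str = ""

    def __post_init__(self):
        for tr in self.traces:
            if tr.n_frames >= 2 and abs(tr.dt - self.dt) > DT_TOL:
                raise FormatError(
                    f"trace {tr.trace_id!r}: dt {tr.dt} differs from set dt {self.dt}"
                )

    def __len__(self) -> int:
        return len(self.traces)

    def __iter__(self):
        return iter(self.traces)

    def subset(self, ids) -> "TraceSet":
        ids = set(ids)
        return TraceSet(
            [tr for tr in self.traces if tr.trace_id in ids], self.dt, self.condition
        )


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------

def write_trace_csv(trace_set: TraceSet, path) -> None:
    """Write a trace set in the long CSV dialect."""
    frames = []
    for tr in trace_set:
        frames.append(
            pd.DataFrame(
                {
                    "trace_id": tr.trace_id,
                    "frame": np.arange(tr.n_frames, dtype=int),
                    "time_s": tr.time_s,
                    "donor": tr.donor,
                    "acceptor": tr.acceptor,
                }
            )
        )
    df = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=CSV_COLUMNS)
    )
    df.to_csv(path, index=False)


def read_trace_csv(path, condition: str = "") -> TraceSet:
    """Read a long-format trace CSV, validating the dialect.

    Raises
    ------
    FormatError
        On missing columns, non-monotone time, or ragged traces; the message
        names the offending trace_id.
    """
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(f"{path}: unreadable CSV ({exc})") from exc
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    traces = []
    for tid, grp in df.groupby("trace_id", sort=False):
        grp = grp.sort_values("frame")
        if not np.array_equal(grp["frame"].to_numpy(), np.arange(len(grp))):
            raise FormatError(f"trace {tid!r}: frame indices not contiguous from 0")
        traces.append(
            Trace(
                str(tid),
                grp["time_s"].to_numpy(float),
                grp["donor"].to_numpy(float),
                grp["acceptor"].to_numpy(float),
            )
        )
    if not traces:
        return TraceSet([], float("nan"), condition)
    dts = [tr.dt for tr in traces if tr.n_frames >= 2]
    dt = dts[0] if dts else float("nan")
    return TraceSet(traces, dt, condition)


# ---------------------------------------------------------------------------
# Binary dialect
# ---------------------------------------------------------------------------

_HEADER = struct.Struct("<iif")  # n_frames, n_traces, dt


def write_trace_binary(trace_set: TraceSet, path) -> None:
    """Write the little-endian binary dialect (int16 intensities).

    All traces must share one length; intensities are rounded to the nearest
    integer and must fit int16.
    """
    lengths = {tr.n_frames for tr in trace_set}
    if len(lengths) > 1:
        raise FormatError(f"binary dialect requires equal trace lengths, got {sorted(lengths)}")
    n_frames = lengths.pop() if lengths else 0
    with open(path, "wb") as fh:
        fh.write(_HEADER.pack(n_frames, len(trace_set), float(trace_set.dt)))
        for tr in trace_set:
            d = np.rint(tr.donor).astype("<i2")
            a = np.rint(tr.acceptor).astype("<i2")
            fh.write(d.tobytes())
            fh.write(a.tobytes())


def read_trace_binary(path, condition: str = "") -> TraceSet:
    """Read the binary dialect; trace ids are regenerated as ``trace_%04d``.

    Raises
    ------
    CorruptFileError
        If the payload size does not match the header.
    """
    raw = Path(path).read_bytes()
    if len(raw) < _HEADER.size:
        raise CorruptFileError(f"{path}: shorter than header ({len(raw)} bytes)")
    n_frames, n_traces, dt = _HEADER.unpack_from(raw)
    if n_frames < 0 or n_traces < 0:
        raise CorruptFileError(f"{path}: negative counts in header")
    expected = _HEADER.size + n_traces * n_frames * 2 * 2
    if len(raw) != expected:
        raise CorruptFileError(
            f"{path}: size mismatch (header implies {expected} bytes, file has {len(raw)})"
        )
    payload = np.frombuffer(raw, dtype="<i2", offset=_HEADER.size)
    payload = payload.reshape(n_traces, 2, n_frames)
    time_s = np.arange(n_frames) * dt
    traces = [
        Trace(f"trace_{i:04d}", time_s, payload[i, 0].astype(float), payload[i, 1].astype(float))
        for i in range(n_traces)
    ]
    return TraceSet(traces, float(dt), condition)
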