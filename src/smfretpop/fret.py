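"""Per-frame apparent FRET efficiency and static/dynamic classification.

The apparent efficiency is the uncorrected intensity ratio
E = I_acceptor / (I_acceptor + I_donor), optionally after background
subtraction (off by default). Frames at or after the first photobleach are
excluded: after acceptor bleach the ratio collapses to ~0 (donor-only
regime) and would distort the population histogram.

A trace is *dynamic* when its idealized FRET series shows at least one
credible transition between the low and high state. Idealization is
deliberately simple — a 3-frame median filter followed by hysteresis
thresholding at the midpoint with a +-0.05 dead band — because only the
presence and count of transitions is analyzed, not rate constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import medfilt
from statsmodels.stats.proportion import proportion_confint

from .errors import EmptySeriesError, UnclassifiableError
from .qc import QCResult
from .trace_io import Trace

#: reporting clamp for background-subtracted efficiencies
E_CLAMP = (-0.5, 1.5)


@dataclass
class FretSeries:
    """Apparent FRET values on the valid (pre-bleach) frames of one trace."""

    trace_id: str
    frames: np.ndarray
    e_app: np.ndarray
    n_excluded: int = 0
    is_dynamic: bool | None = None
    n_transitions: int = 0
    dwell_records: list[tuple[int, float]] = field(default_factory=list)
    dt: float = float("nan")

    @property
    def n_valid(self) -> int:
        return len(self.e_app)


def compute_fret(
    trace: Trace,
    qc: QCResult | None = None,
    background_donor: float = 0.0,
    background_acceptor: float = 0.0,
) -> FretSeries:
    """Apparent FRET series of an accepted trace.

    Frames from the first bleach (acceptor or donor, whichever the QC step
    located first) onward are dropped; frames whose corrected total
    intensity is <= 0 are excluded and counted in ``n_excluded``.

    Raises
    ------
    EmptySeriesError
        If no valid frames remain.
    """
    end = trace.n_frames
    if qc is not None and qc.first_bleach_frame is not None:
        end = qc.first_bleach_frame
    don = trace.donor[:end] - background_donor
    acc = trace.acceptor[:end] - background_acceptor
    denom = don + acc
    keep = denom > 0
    n_excluded = int(end - np.count_nonzero(keep))
    if not np.any(keep):
        raise EmptySeriesError(f"trace {trace.trace_id!r}: no valid frames")
    e = acc[keep] / denom[keep]
    e = np.clip(e, *E_CLAMP)
    return FretSeries(
        trace_id=trace.trace_id,
        frames=np.flatnonzero(keep),
        e_app=e,
        n_excluded=n_excluded,
        dt=trace.dt,
    )


def _hysteresis_idealize(e: np.ndarray, low: float, high: float, dead_band: float) -> np.ndarray:
    """Two-state idealization with a dead band around the midpoint."""
    mid = 0.5 * (low + high)
    up, down = mid + dead_band, mid - dead_band
    states = np.empty(len(e), dtype=int)
    state = 1 if e[0] > mid else 0
    for i, val in enumerate(e):
        if state == 0 and val > up:
            state = 1
        elif state == 1 and val < down:
            state = 0
        states[i] = state
    return states


def classify_dynamic(
    series: FretSeries,
    low_state: float = 0.4,
    high_state: float = 0.6,
    dead_band: float = 0.05,
    min_dwell: int = 3,
) -> FretSeries:
    """Decide static vs dynamic from the idealized FRET series (in place).

    A transition counts when both flanking dwells last at least
    ``min_dwell`` frames; a trace with >= 1 such transition is dynamic.

    Raises
    ------
    UnclassifiableError
        Fewer than 10 valid frames.
    """
    if series.n_valid < 10:
        raise UnclassifiableError(
            f"trace {series.trace_id!r}: {series.n_valid} valid frames < 10"
        )
    e = medfilt(series.e_app, 3)
    states = _hysteresis_idealize(e, low_state, high_state, dead_band)
    # run-length encode
    change = np.flatnonzero(np.diff(states)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(states)]])
    lengths = ends - starts
    seg_states = states[starts]
    n_transitions = 0
    for i in range(1, len(starts)):
        if lengths[i - 1] >= min_dwell and lengths[i] >= min_dwell:
            n_transitions += 1
    series.is_dynamic = n_transitions >= 1
    series.n_transitions = n_transitions
    dt = series.dt if np.isfinite(series.dt) else 1.0
    series.dwell_records = [
        (int(s), float(n * dt)) for s, n in zip(seg_states, lengths)
    ]
    return series


def fraction_dynamic(series_list) -> tuple[float, tuple[float, float]]:
    """Dynamic fraction with its Wilson 95% confidence interval.

    Accepts classified :class:`FretSeries` objects or plain booleans.
    """
    flags = []
    for s in series_list:
        flag = s.is_dynamic if isinstance(s, FretSeries) else bool(s)
        if flag is None:
            raise UnclassifiableError(f"trace {s.trace_id!r} has not been classified")
        flags.append(bool(flag))
    n = len(flags)
    if n < 1:
        raise UnclassifiableError("no classified traces")
    count = sum(flags)
    lo, hi = proportion_confint(count, n, alpha=0.05, method="wilson")
    return count / n, (float(lo), float(hi))
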