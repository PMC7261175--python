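"""Trace selection: photobleaching-step detection and anti-correlation.

A trace is analyzable when it shows the signature of a single molecule with
one donor and one acceptor: a single photobleaching step in each channel,
and/or anti-correlated donor/acceptor intensity changes at a constant summed
intensity (the fingerprint of genuine energy transfer). Selection applies
the literal OR of the two criteria; an AND-strict mode is available.

Step detection is greedy binary segmentation: recursively fit the best
single-changepoint piecewise-constant model (minimum residual sum of
squares) and accept a split while its step magnitude exceeds ``step_sigma``
times the noise SD. The noise SD is estimated robustly as the median
absolute deviation of first differences divided by sqrt(2) (scaled to a
Gaussian SD), which is insensitive to the steps themselves. A downward step
is the *terminal bleach* if the mean intensity from the step to the end of
the trace is within 2 noise SDs of background.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
import warnings

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from .errors import TooShortError, ZeroVarianceError
from .trace_io import Trace, TraceSet

#: rejection reason codes
REASONS = ("multi_step", "no_signal", "too_short", "no_anticorr", "high_cv")


@dataclass(frozen=True)
class QCConfig:
    """Thresholds of the selection criteria (all config-exposed).

    anticorr_thresh/cv_max bound the anti-correlation branch; step_sigma is
    the changepoint magnitude rule in noise SDs; min_frames the shortest
    analyzable series.
    """

    anticorr_thresh: float = -0.3
    cv_max: float = 0.2
    step_sigma: float = 3.0
    background_donor: float = 0.0
    background_acceptor: float = 0.0
    min_frames: int = 10
    min_segment: int = 2
    strict_and: bool = False


@dataclass
class QCResult:
    """Per-trace QC verdict with the evidence behind it."""

    trace_id: str
    donor_bleach_frame: int | None
    acceptor_bleach_frame: int | None
    n_steps_donor: int
    n_steps_acceptor: int
    anticorr_r: float
    total_cv: float
    accepted: bool
    reason: str

    @property
    def first_bleach_frame(self) -> int | None:
        frames = [f for f in (self.donor_bleach_frame, self.acceptor_bleach_frame) if f is not None]
        return min(frames) if frames else None


def estimate_noise_sd(y) -> float:
    """Robust per-frame noise SD from first differences (MAD-based)."""
    y = np.asarray(y, dtype=float)
    if len(y) < 2:
        return 0.0
    return float(1.4826 * np.median(np.abs(np.diff(y))) / np.sqrt(2.0))


def _best_split(y: np.ndarray, min_segment: int):
    """Best single changepoint of a segment by least squares.

    Returns (index, left_mean, right_mean) where ``index`` is the first
    frame of the right segment, or None if the segment is too short.
    """
    n = len(y)
    if n < 2 * min_segment:
        return None
    c = np.cumsum(y)
    total = c[-1]
    k = np.arange(min_segment, n - min_segment + 1)
    left = c[k - 1]
    right = total - left
    # maximizing explained sum of squares == minimizing RSS
    score = left * left / k + right * right / (n - k)
    j = int(np.argmax(score))
    idx = int(k[j])
    return idx, float(left[j] / idx), float(right[j] / (n - idx))


def detect_steps(y, noise_sd: float | None = None, step_sigma: float = 3.0, min_segment: int = 2):
    """All changepoints found by recursive binary segmentation.

    Returns a sorted list of (frame, left_mean, right_mean); the local means
    are those of the two flanking fitted segments at the final segmentation.
    """
    y = np.asarray(y, dtype=float)
    if len(y) < 10:
        raise TooShortError(f"series of {len(y)} frames is shorter than 10")
    if noise_sd is None:
        noise_sd = estimate_noise_sd(y)
    thresh = step_sigma * max(noise_sd, 1e-12)
    cps: list[int] = []

    def recurse(lo: int, hi: int):
        split = _best_split(y[lo:hi], min_segment)
        if split is None:
            return
        idx, lm, rm = split
        if abs(rm - lm) <= thresh:
            return
        cps.append(lo + idx)
        recurse(lo, lo + idx)
        recurse(lo + idx, hi)

    recurse(0, len(y))
    cps.sort()
    # recompute flanking-segment means on the final segmentation
    bounds = [0] + cps + [len(y)]
    out = []
    for i, cp in enumerate(cps):
        lm = float(np.mean(y[bounds[i]:cp]))
        rm = float(np.mean(y[cp:bounds[i + 2]]))
        out.append((cp, lm, rm))
    return out


def detect_bleach_steps(
    y,
    noise_sd: float | None = None,
    step_sigma: float = 3.0,
    min_segment: int = 2,
) -> list[int]:
    """Frames of downward steps (first frame of the lower level), in order."""
    return [cp for cp, lm, rm in detect_steps(y, noise_sd, step_sigma, min_segment) if rm < lm]


def terminal_bleach_frame(
    y, steps: list[int], background: float, noise_sd: float
) -> int | None:
    """The bleach frame: last downward step whose tail mean sits at background."""
    y = np.asarray(y, dtype=float)
    if not steps:
        return None
    last = steps[-1]
    if np.mean(y[last:]) <= background + 2.0 * noise_sd:
        return last
    return None


def anticorrelation_score(donor, acceptor, window: slice | None = None):
    """(Pearson r of first differences, CV of total intensity) over a window.

    Raises
    ------
    TooShortError
        Window shorter than 10 frames.
    ZeroVarianceError
        A channel's differences have zero variance.
    """
    donor = np.asarray(donor, dtype=float)
    acceptor = np.asarray(acceptor, dtype=float)
    if window is not None:
        donor, acceptor = donor[window], acceptor[window]
    if len(donor) < 10:
        raise TooShortError(f"anticorrelation window of {len(donor)} frames is shorter than 10")
    dd = np.diff(donor)
    da = np.diff(acceptor)
    if np.std(dd) == 0 or np.std(da) == 0:
        raise ZeroVarianceError("zero-variance channel: correlation undefined")
    r = float(np.corrcoef(dd, da)[0, 1])
    total = donor + acceptor
    mean = float(np.mean(total))
    cv = float(np.std(total) / mean) if mean != 0 else float("inf")
    return r, cv


def _has_signal(y: np.ndarray, background: float, noise_sd: float) -> bool:
    """True if a 5-frame smoothed window ever rises clearly above background."""
    smoothed = uniform_filter1d(np.asarray(y, dtype=float), 5, mode="nearest")
    return bool(np.max(smoothed) > background + 3.0 * max(noise_sd, 1e-12))


def qc_trace(trace: Trace, config: QCConfig = QCConfig()) -> QCResult:
    """Apply both selection criteria to one trace."""
    n = trace.n_frames
    base = dict(
        trace_id=trace.trace_id,
        donor_bleach_frame=None,
        acceptor_bleach_frame=None,
        n_steps_donor=0,
        n_steps_acceptor=0,
        anticorr_r=float("nan"),
        total_cv=float("nan"),
    )
    if n < config.min_frames:
        return QCResult(**base, accepted=False, reason="too_short")

    sd_d = estimate_noise_sd(trace.donor)
    sd_a = estimate_noise_sd(trace.acceptor)
    steps_d = detect_bleach_steps(trace.donor, sd_d, config.step_sigma, config.min_segment)
    steps_a = detect_bleach_steps(trace.acceptor, sd_a, config.step_sigma, config.min_segment)
    bleach_d = terminal_bleach_frame(trace.donor, steps_d, config.background_donor, sd_d)
    bleach_a = terminal_bleach_frame(trace.acceptor, steps_a, config.background_acceptor, sd_a)
    base.update(
        donor_bleach_frame=bleach_d,
        acceptor_bleach_frame=bleach_a,
        n_steps_donor=len(steps_d),
        n_steps_acceptor=len(steps_a),
    )

    if not (
        _has_signal(trace.donor, config.background_donor, sd_d)
        and _has_signal(trace.acceptor, config.background_acceptor, sd_a)
    ):
        return QCResult(**base, accepted=False, reason="no_signal")

    first_bleach = min(
        [f for f in (bleach_d, bleach_a) if f is not None], default=n
    )
    r = cv = float("nan")
    window_ok = first_bleach >= config.min_frames
    if window_ok:
        try:
            r, cv = anticorrelation_score(trace.donor, trace.acceptor, slice(0, first_bleach))
        except ZeroVarianceError:
            window_ok = False
    base.update(anticorr_r=r, total_cv=cv)

    if config.strict_and:
        bleach_ok = (
            len(steps_d) == 1 and len(steps_a) == 1
            and bleach_d is not None and bleach_a is not None
        )
    else:
        bleach_ok = len(steps_d) == 1 and len(steps_a) <= 1 and bleach_d is not None
    anticorr_ok = window_ok and r <= config.anticorr_thresh and cv <= config.cv_max

    if bleach_ok or anticorr_ok:
        reason = "ok" if first_bleach > 0 else "accepted_empty"
        return QCResult(**base, accepted=True, reason=reason)
    if len(steps_d) > 1 or len(steps_a) > 1:
        reason = "multi_step"
    elif not window_ok:
        reason = "too_short"
    elif cv > config.cv_max:
        reason = "high_cv"
    else:
        reason = "no_anticorr"
    return QCResult(**base, accepted=False, reason=reason)


def qc_all(trace_set: TraceSet, config: QCConfig = QCConfig()) -> list[QCResult]:
    """QC verdicts for every trace, in input order."""
    return [qc_trace(tr, config) for tr in trace_set]


def qc_table(results: list[QCResult]) -> pd.DataFrame:
    """Tabulate QC results (one row per trace, all QCResult fields)."""
    if not results:
        return pd.DataFrame(columns=list(QCResult.__dataclass_fields__))
    return pd.DataFrame([asdict(res) for res in results])


def select_traces(
    trace_set: TraceSet, config: QCConfig = QCConfig()
) -> tuple[TraceSet, pd.DataFrame]:
    """Apply QC to every trace; return the accepted subset and a report table."""
    if len(trace_set) == 0:
        warnings.warn("empty trace set passed to QC", UserWarning)
        return trace_set, qc_table([])
    results = qc_all(trace_set, config)
    accepted_ids = [res.trace_id for res in results if res.accepted]
    return trace_set.subset(accepted_ids), qc_table(results)
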