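"""Synthetic smFRET trace and titration generator with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes for a two-domain protein switching between an open (low-FRET) and a
closed (high-FRET) conformation:

* Markovian two-state switching simulated exactly in continuous time
  (Gillespie event times); each camera frame reports the time-weighted mean
  FRET over its exposure, so exchange faster than the frame interval averages
  out exactly as it would on a real camera.
* Constant total emission intensity split between acceptor and donor in
  proportion E : (1-E), plus per-channel additive Gaussian read noise and an
  optional constant background.
* Single-step photobleaching of each fluorophore with independent exponential
  waiting times. After acceptor bleach the donor recovers the full intensity;
  after donor bleach both channels fall to background.
* Static traces are rate-zero chains pinned in one state (their histograms
  still carry shot noise); an optional "aggregate" contaminant with two
  fluorophore pairs produces the two-step bleaching that QC must reject.
* Concentration series in which the bound fraction follows a single-site
  binding law, shifting the open/closed population balance.

All randomness flows from one seed (or an explicit numpy Generator); a fixed
seed reproduces every trace bit for bit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .binding import BindingCurve, quadratic_bound_fraction
from .errors import DegenerateSignalWarning, ParameterError
from .trace_io import Trace, TraceSet

OPEN, CLOSED = 0, 1


def as_rng(seed) -> np.random.Generator:
    """Coerce an int seed or Generator into a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class KineticParams:
    """Two-state open/closed switching model.

    Parameters
    ----------
    k_oc, k_co : float
        open->closed and closed->open rate constants (s^-1).
    e_open, e_closed : float
        Apparent FRET efficiency of each state (dimensionless). Defaults are
        the 0.4 / 0.6 values characteristic of the side-by-side and
        back-to-back tandem-RRM arrangements.
    """

    k_oc: float
    k_co: float
    e_open: float = 0.4
    e_closed: float = 0.6

    def __post_init__(self):
        if self.k_oc < 0 or self.k_co < 0:
            raise ParameterError(f"rates must be >= 0, got k_oc={self.k_oc}, k_co={self.k_co}")
        if not (0.0 <= self.e_open < self.e_closed <= 1.0):
            raise ParameterError(
                f"need 0 <= e_open < e_closed <= 1, got {self.e_open}, {self.e_closed}"
            )

    @property
    def p_closed_eq(self) -> float:
        """Stationary closed-state occupancy k_oc/(k_oc+k_co)."""
        k = self.k_oc + self.k_co
        if k == 0:
            raise ParameterError("stationary occupancy undefined for a frozen (0,0) chain")
        return self.k_oc / k

    def pinned(self, state: int) -> "KineticParams":
        """Rate-zero copy used for static traces (state is set at start)."""
        return replace(self, k_oc=0.0, k_co=0.0)


@dataclass(frozen=True)
class EmissionParams:
    """Camera/photophysics parameters of the emission model.

    i_total is the mean total signal (counts/frame) shared by the two
    channels; sigma_read the additive per-channel noise SD; dt the frame
    interval in seconds (0.1 s, i.e. a 100 ms exposure). Photobleach waiting
    times are exponential with the given rates (s^-1); a rate of 0 disables
    bleaching of that dye. ``leakage`` mixes that fraction of donor signal
    into the acceptor channel (0 by default: the analysis works on apparent
    FRET, uncorrected by design).
    """

    i_total: float = 1000.0
    sigma_read: float = 40.0
    background: float = 0.0
    dt: float = 0.1
    n_frames: int = 600
    bleach_rate_donor: float = 0.03
    bleach_rate_acceptor: float = 0.05
    leakage: float = 0.0

    def __post_init__(self):
        if self.dt <= 0:
            raise ParameterError(f"dt must be > 0, got {self.dt}")
        if self.i_total <= 0:
            raise ParameterError(f"i_total must be > 0, got {self.i_total}")
        if self.n_frames < 1:
            raise ParameterError(f"n_frames must be >= 1, got {self.n_frames}")
        if self.sigma_read < 0 or self.bleach_rate_donor < 0 or self.bleach_rate_acceptor < 0:
            raise ParameterError("noise SD and bleach rates must be >= 0")


@dataclass
class StatePath:
    """Exact continuous-time realization of the two-state chain, binned to frames.

    ``frac_closed`` is the fraction of each exposure spent closed;
    ``e_mean`` the corresponding time-weighted mean FRET; ``states`` the
    majority state per frame. ``event_times``/``event_states`` give the jump
    chain (state entered at each time, starting at t=0); ``dwells`` the
    (state, duration) sequence, the final dwell right-censored at the end of
    the observation window.
    """

    states: np.ndarray
    frac_closed: np.ndarray
    e_mean: np.ndarray
    event_times: np.ndarray
    event_states: np.ndarray
    dwells: list[tuple[int, float]]

    @property
    def n_transitions(self) -> int:
        return len(self.event_times) - 1


@dataclass
class GroundTruth:
    """Per-trace generative record enabling parameter-recovery tests."""

    states: np.ndarray
    e_true: np.ndarray
    donor_bleach_frame: int | None
    acceptor_bleach_frame: int | None
    is_dynamic: bool
    is_aggregate: bool = False
    n_transitions: int = 0

    @property
    def first_bleach_frame(self) -> int | None:
        frames = [f for f in (self.donor_bleach_frame, self.acceptor_bleach_frame) if f is not None]
        return min(frames) if frames else None


@dataclass
class DatasetGroundTruth:
    """Dataset-level ground truth: per-trace records plus the target p_closed."""

    per_trace: list[GroundTruth]
    p_closed: float

    @property
    def n_dynamic(self) -> int:
        return sum(gt.is_dynamic for gt in self.per_trace)


def simulate_state_path(
    kinetics: KineticParams,
    n_frames: int,
    dt: float,
    seed,
    start_state: int | None = None,
) -> StatePath:
    """Gillespie simulation of the two-state chain with exposure averaging.

    The chain is simulated in continuous time with exact exponential event
    times; each frame then reports the time-weighted mean FRET over its
    exposure window, so transitions faster than ``dt`` blur within a frame
    rather than being resampled.
    """
    if n_frames < 1:
        raise ParameterError(f"n_frames must be >= 1, got {n_frames}")
    if dt <= 0:
        raise ParameterError(f"dt must be > 0, got {dt}")
    rng = as_rng(seed)
    if start_state is None:
        if kinetics.k_oc + kinetics.k_co > 0:
            p = kinetics.p_closed_eq
        else:
            p = 0.5
        start_state = CLOSED if rng.random() < p else OPEN
    horizon = n_frames * dt
    times = [0.0]
    states = [start_state]
    t, s = 0.0, start_state
    while True:
        k = kinetics.k_oc if s == OPEN else kinetics.k_co
        if k <= 0:
            break
        t += rng.exponential(1.0 / k)
        if t >= horizon:
            break
        s = CLOSED if s == OPEN else OPEN
        times.append(t)
        states.append(s)
    times_arr = np.asarray(times)
    states_arr = np.asarray(states, dtype=int)

    # cumulative closed-state time at the dwell knots, then interpolate at
    # frame edges: frame occupancy = (C(t_{i+1}) - C(t_i)) / dt
    bounds = np.append(times_arr, horizon)
    durations = np.diff(bounds)
    closed_time = np.concatenate([[0.0], np.cumsum(durations * (states_arr == CLOSED))])
    edges = np.arange(n_frames + 1) * dt
    c_at_edges = np.interp(edges, bounds, closed_time)
    frac_closed = np.diff(c_at_edges) / dt
    e_mean = kinetics.e_open + frac_closed * (kinetics.e_closed - kinetics.e_open)
    frame_states = (frac_closed >= 0.5).astype(int)
    dwells = [(int(st), float(d)) for st, d in zip(states_arr, durations)]
    return StatePath(frame_states, frac_closed, e_mean, times_arr, states_arr, dwells)


def _bleach_frame(rate: float, dt: float, n_frames: int, rng) -> int | None:
    """Frame index from which a dye is dark, or None if it survives the trace."""
    if rate <= 0:
        return None
    t = rng.exponential(1.0 / rate)
    f = int(math.floor(t / dt))
    return f if f < n_frames else None


def simulate_trace(
    kinetics: KineticParams,
    emission: EmissionParams,
    seed,
    start_state: int | None = None,
    trace_id: str = "trace_0000",
) -> tuple[Trace, GroundTruth]:
    """Simulate one donor/acceptor trace plus its generative ground truth.

    Before bleaching, acceptor = background + E*i_total and donor =
    background + (1-E)*i_total (E exposure-averaged), each with additive
    Gaussian read noise. After acceptor bleach the acceptor falls to
    background and the donor rises to background + i_total; after donor
    bleach both channels fall to background.
    """
    rng = as_rng(seed)
    path = simulate_state_path(kinetics, emission.n_frames, emission.dt, rng, start_state)
    f_d = _bleach_frame(emission.bleach_rate_donor, emission.dt, emission.n_frames, rng)
    f_a = _bleach_frame(emission.bleach_rate_acceptor, emission.dt, emission.n_frames, rng)

    e = path.e_mean
    bg = emission.background
    acc = e * emission.i_total + emission.leakage * (1.0 - e) * emission.i_total
    don = (1.0 - e) * emission.i_total
    fd = emission.n_frames if f_d is None else f_d
    fa = emission.n_frames if f_a is None else f_a
    if fa < fd:
        acc[fa:] = emission.leakage * emission.i_total
        don[fa:] = emission.i_total
    acc[fd:] = 0.0
    don[fd:] = 0.0
    acc += bg
    don += bg
    if emission.sigma_read > 0:
        don = don + rng.normal(0.0, emission.sigma_read, emission.n_frames)
        acc = acc + rng.normal(0.0, emission.sigma_read, emission.n_frames)

    time_s = np.arange(emission.n_frames) * emission.dt
    trace = Trace(trace_id, time_s, don, acc)
    truth = GroundTruth(
        states=path.states,
        e_true=path.e_mean,
        donor_bleach_frame=f_d,
        acceptor_bleach_frame=f_a,
        is_dynamic=(kinetics.k_oc > 0 and kinetics.k_co > 0),
        n_transitions=path.n_transitions,
    )
    return trace, truth


def simulate_aggregate_trace(
    kinetics: KineticParams,
    emission: EmissionParams,
    seed,
    trace_id: str = "trace_0000",
) -> tuple[Trace, GroundTruth]:
    """Contaminant trace: two independent fluorophore pairs on one spot.

    The summed channels show staircase (two-step) photobleaching, which the
    QC single-step criterion must reject.
    """
    rng = as_rng(seed)
    t1, g1 = simulate_trace(kinetics, emission, rng, trace_id=trace_id)
    t2, g2 = simulate_trace(kinetics, emission, rng, trace_id=trace_id)
    don = t1.donor + t2.donor - emission.background
    acc = t1.acceptor + t2.acceptor - emission.background
    trace = Trace(trace_id, t1.time_s, don, acc)
    truth = GroundTruth(
        states=g1.states,
        e_true=(g1.e_true + g2.e_true) / 2.0,
        donor_bleach_frame=g1.donor_bleach_frame,
        acceptor_bleach_frame=g1.acceptor_bleach_frame,
        is_dynamic=g1.is_dynamic,
        is_aggregate=True,
        n_transitions=g1.n_transitions + g2.n_transitions,
    )
    return trace, truth


def simulate_dataset(
    kinetics: KineticParams,
    emission: EmissionParams,
    n_traces: int,
    frac_dynamic: float,
    seed,
    p_closed: float | None = None,
    frac_aggregate: float = 0.0,
    condition: str = "",
) -> tuple[TraceSet, DatasetGroundTruth]:
    """Simulate a trace set mixing dynamic and static molecules.

    A fraction ``frac_dynamic`` of traces evolves under ``kinetics``; the
    rest are pinned (rate-zero) in the closed state with probability
    ``p_closed`` (default: the stationary occupancy of ``kinetics``).
    Dynamic traces start from the same Bernoulli(p_closed) draw.
    ``frac_aggregate`` adds two-pair contaminant traces for QC tests.
    """
    if n_traces < 1:
        raise ParameterError(f"n_traces must be >= 1, got {n_traces}")
    if not 0.0 <= frac_dynamic <= 1.0:
        raise ParameterError(f"frac_dynamic must be in [0,1], got {frac_dynamic}")
    if not 0.0 <= frac_aggregate <= 1.0:
        raise ParameterError(f"frac_aggregate must be in [0,1], got {frac_aggregate}")
    if p_closed is None:
        p_closed = kinetics.p_closed_eq
    if not 0.0 <= p_closed <= 1.0:
        raise ParameterError(f"p_closed must be in [0,1], got {p_closed}")

    rng = as_rng(seed)
    static_kin = kinetics.pinned(CLOSED)
    traces, truths = [], []
    for i in range(n_traces):
        tid = f"trace_{i:04d}"
        aggregate = rng.random() < frac_aggregate
        dynamic = rng.random() < frac_dynamic
        start = CLOSED if rng.random() < p_closed else OPEN
        if aggregate:
            tr, gt = simulate_aggregate_trace(kinetics, emission, rng, trace_id=tid)
        elif dynamic:
            tr, gt = simulate_trace(kinetics, emission, rng, start_state=start, trace_id=tid)
        else:
            tr, gt = simulate_trace(static_kin, emission, rng, start_state=start, trace_id=tid)
        tr.meta["condition"] = condition
        traces.append(tr)
        truths.append(gt)
    return (
        TraceSet(traces, emission.dt, condition),
        DatasetGroundTruth(truths, p_closed),
    )


def simulate_fret_titration(
    kd: float,
    concentrations,
    p_closed_free: float,
    p_closed_bound: float,
    kinetics: KineticParams,
    emission: EmissionParams,
    n_traces: int,
    seed,
    frac_dynamic: float = 0.0,
) -> dict[float, tuple[TraceSet, DatasetGroundTruth]]:
    """Per-concentration trace sets whose population balance follows binding.

    At titrant concentration c the bound fraction is the binding hyperbola
    c/(kd+c); the mixture closed probability is the bound-fraction-weighted
    average of ``p_closed_bound`` and ``p_closed_free``. Static traces are
    pinned closed with that probability; dynamic traces switch with the
    total rate (k_oc + k_co) of ``kinetics`` but with the stationary
    occupancy set to the same mixture probability, i.e. ligand binding
    shifts the conformational equilibrium rather than freezing molecules.
    """
    if kd <= 0:
        raise ParameterError(f"kd must be > 0, got {kd}")
    concentrations = np.asarray(concentrations, dtype=float)
    if np.any(concentrations < 0):
        raise ParameterError("concentrations must be >= 0")
    rng = as_rng(seed)
    k_tot = kinetics.k_oc + kinetics.k_co
    out: dict[float, tuple[TraceSet, DatasetGroundTruth]] = {}
    for c in concentrations:
        fb = c / (kd + c)
        p_c = (1.0 - fb) * p_closed_free + fb * p_closed_bound
        kin_c = replace(kinetics, k_oc=k_tot * p_c, k_co=k_tot * (1.0 - p_c))
        ts, gt = simulate_dataset(
            kin_c,
            emission,
            n_traces,
            frac_dynamic,
            rng,
            p_closed=p_c,
            condition=f"c={c:g}nM",
        )
        out[float(c)] = (ts, gt)
    return out


def simulate_anisotropy_titration(
    kd: float,
    r_free: float,
    r_bound: float,
    probe_conc: float,
    protein_concs,
    noise_sd: float,
    seed,
) -> BindingCurve:
    """Fluorescence-anisotropy titration of a labeled probe with protein.

    The bound fraction follows the single-site ligand-depletion (quadratic)
    solution, appropriate when the probe concentration is comparable to K_D;
    Gaussian noise of SD ``noise_sd`` is added to the anisotropy.
    """
    if kd <= 0:
        raise ParameterError(f"kd must be > 0, got {kd}")
    if probe_conc <= 0:
        raise ParameterError(f"probe_conc must be > 0, got {probe_conc}")
    if r_bound == r_free:
        warnings.warn(
            "r_bound == r_free: titration carries no signal", DegenerateSignalWarning
        )
    rng = as_rng(seed)
    protein = np.asarray(protein_concs, dtype=float)
    if np.any(protein < 0):
        raise ParameterError("protein concentrations must be >= 0")
    fb = quadratic_bound_fraction(protein, probe_conc, kd)
    r = r_free + (r_bound - r_free) * fb
    if noise_sd > 0:
        r = r + rng.normal(0.0, noise_sd, len(protein))
    return BindingCurve(x=protein, y=r, mode="anisotropy", probe_conc=probe_conc)
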