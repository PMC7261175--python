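"""Step detection, anti-correlation scoring, and trace selection."""

import numpy as np
import pytest

from smfretpop import (
    EmissionParams,
    KineticParams,
    QCConfig,
    TooShortError,
    Trace,
    ZeroVarianceError,
    anticorrelation_score,
    detect_bleach_steps,
    estimate_noise_sd,
    qc_trace,
    select_traces,
    simulate_dataset,
    simulate_trace,
    terminal_bleach_frame,
)
from smfretpop.qc import qc_all


def _mk_trace(donor, acceptor, dt=0.1, tid="t0"):
    n = len(donor)
    return Trace(tid, np.arange(n) * dt, donor, acceptor)


def test_noise_sd_estimate_is_robust_to_steps(rng):
    y = np.concatenate([np.full(300, 1000.0), np.zeros(300)])
    y += rng.normal(0, 40, 600)
    est = estimate_noise_sd(y)
    assert abs(est - 40) / 40 < 0.15


def test_constant_series_has_no_steps(rng):
    y = 500 + rng.normal(0, 30, 400)
    assert detect_bleach_steps(y) == []


def test_planted_step_located_within_two_frames(rng):
    y = np.concatenate([np.full(200, 1000.0), np.zeros(400)])
    y += rng.normal(0, 40, 600)
    steps = detect_bleach_steps(y)
    assert len(steps) == 1
    assert abs(steps[0] - 200) <= 2
    assert terminal_bleach_frame(y, steps, 0.0, estimate_noise_sd(y)) == steps[0]


def test_two_step_staircase_detected(rng):
    y = np.concatenate([np.full(200, 1000.0), np.full(200, 500.0), np.zeros(200)])
    y += rng.normal(0, 40, 600)
    steps = detect_bleach_steps(y)
    assert len(steps) == 2
    assert abs(steps[0] - 200) <= 2 and abs(steps[1] - 400) <= 2


def test_short_series_rejected():
    with pytest.raises(TooShortError):
        detect_bleach_steps(np.ones(5))


def test_perfect_anticorrelation(rng):
    donor = 500 + 100 * np.sin(np.arange(200))
    acceptor = 1000.0 - donor
    r, cv = anticorrelation_score(donor, acceptor)
    assert r == pytest.approx(-1.0)
    assert cv == pytest.approx(0.0, abs=1e-12)


def test_independent_noise_uncorrelated(rng):
    donor = rng.normal(500, 40, 10_000)
    acceptor = rng.normal(500, 40, 10_000)
    r, _ = anticorrelation_score(donor, acceptor)
    assert abs(r) < 0.05


def test_zero_variance_channel_raises():
    with pytest.raises(ZeroVarianceError):
        anticorrelation_score(np.ones(50), np.arange(50.0))


def test_dynamic_trace_anticorrelation_matches_exposure_model():
    """Transitions split across two frame differences give
    E[r] = -x/(2*sigma^2 + x) with x = f*dt*(2/3)*(dE*I)^2; at k_oc=k_co=0.5/s,
    SNR 25 this is ~ -0.29."""
    kin = KineticParams(0.5, 0.5)
    emi = EmissionParams(n_frames=5000, bleach_rate_donor=0, bleach_rate_acceptor=0)
    f_trans = 2 * 0.5 * 0.5 / 1.0  # transitions per second
    x = f_trans * emi.dt * (2 / 3) * (0.2 * emi.i_total) ** 2
    expected = -x / (2 * emi.sigma_read**2 + x)
    rs = []
    for seed in range(5):
        tr, _ = simulate_trace(kin, emi, seed=100 + seed)
        r, _ = anticorrelation_score(tr.donor, tr.acceptor)
        rs.append(r)
    assert np.mean(rs) == pytest.approx(expected, abs=0.04)
    assert np.mean(rs) < -0.2


def test_static_single_bleach_set_fully_accepted():
    """Noiseless single-bleach traces: all accepted via the bleach criterion."""
    n = 200
    traces = []
    for i in range(10):
        fa, fd = 60 + 5 * i, 120 + 5 * i
        acc = np.zeros(n)
        don = np.zeros(n)
        acc[:fa] = 600.0
        don[:fa] = 400.0
        don[fa:fd] = 1000.0
        # tiny noise so correlation/steps are defined
        rng = np.random.default_rng(i)
        traces.append(_mk_trace(don + rng.normal(0, 2, n),
                                acc + rng.normal(0, 2, n), tid=f"t{i}"))
    from smfretpop import TraceSet

    accepted, table = select_traces(TraceSet(traces, 0.1))
    assert len(accepted) == 10
    assert set(table.reason) == {"ok"}


def test_aggregate_traces_rejected_multi_step():
    kin = KineticParams(0.0, 0.0)
    emi = EmissionParams()
    ts, gt = simulate_dataset(kin, emi, 60, 0.0, seed=21, p_closed=0.5,
                              frac_aggregate=1.0)
    accepted, table = select_traces(ts)
    # two-pair traces with both visible bleach steps must carry multi_step
    rejected = table[~table.accepted]
    assert len(rejected) > len(ts) * 0.5
    assert (rejected.reason == "multi_step").mean() > 0.5


def test_donor_only_trace_rejected_no_signal(rng):
    don = np.concatenate([np.full(150, 1000.0), np.zeros(150)]) + rng.normal(0, 30, 300)
    acc = rng.normal(0, 30, 300)
    res = qc_trace(_mk_trace(don, acc))
    assert not res.accepted
    assert res.reason == "no_signal"


def test_short_trace_rejected():
    res = qc_trace(_mk_trace(np.ones(5), np.ones(5)))
    assert not res.accepted and res.reason == "too_short"


def test_detected_bleach_matches_ground_truth(static_mixture):
    """Terminal bleach frames within +-2 of ground truth for >= 95% of traces."""
    ts, gt = static_mixture
    hits = total = 0
    for res, truth in zip(qc_all(ts), gt.per_trace):
        f_true = truth.first_bleach_frame
        if f_true is None or not 10 <= f_true <= ts.traces[0].n_frames - 10:
            continue
        total += 1
        det = res.first_bleach_frame
        if det is not None and abs(det - f_true) <= 2:
            hits += 1
    assert total >= 20
    assert hits / total >= 0.95


def test_acceptance_monotone_in_noise():
    """Raising sigma_read on the same event sequences never gains traces."""
    kin = KineticParams(0.0, 0.0)
    for seed in (31, 32, 33):
        counts = []
        for sigma in (20, 40, 80, 160, 320):
            emi = EmissionParams(sigma_read=sigma)
            ts, _ = simulate_dataset(kin, emi, 60, 0.0, seed=seed, p_closed=0.5,
                                     frac_aggregate=0.15)
            accepted, _ = select_traces(ts)
            counts.append(len(accepted))
        assert all(a >= b for a, b in zip(counts, counts[1:]))


def test_empty_set_warns():
    from smfretpop import TraceSet

    with pytest.warns(UserWarning, match="empty"):
        accepted, table = select_traces(TraceSet([], 0.1))
    assert len(accepted) == 0 and table.empty


def test_strict_and_mode_requires_both_bleaches(rng):
    # donor bleaches, acceptor survives the whole window: OR accepts, AND rejects
    n = 300
    acc = np.full(n, 600.0)
    don = np.full(n, 400.0)
    don[200:] = 0.0
    acc[200:] = 0.0  # acceptor dies with donor (FRET-excited)
    tr = _mk_trace(don + rng.normal(0, 20, n), acc + rng.normal(0, 20, n))
    assert qc_trace(tr).accepted
    # now an acceptor with no terminal step at all
    acc2 = np.full(n, 600.0) + rng.normal(0, 20, n)
    don2 = np.full(n, 400.0) + rng.normal(0, 20, n)
    don2[200:] -= 400.0
    tr2 = _mk_trace(don2, acc2)
    res_or = qc_trace(tr2)
    res_and = qc_trace(tr2, QCConfig(strict_and=True))
    assert res_or.accepted and not res_and.accepted
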