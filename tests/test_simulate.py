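"""Generator correctness: exact chain statistics, emission model, determinism."""

import numpy as np
import pytest
from scipy.linalg import expm

from smfretpop import (
    CLOSED,
    OPEN,
    DegenerateSignalWarning,
    EmissionParams,
    KineticParams,
    ParameterError,
    simulate_anisotropy_titration,
    simulate_dataset,
    simulate_fret_titration,
    simulate_state_path,
    simulate_trace,
)


def stationary_occupancy_oracle(k_oc, k_co, t=1e6):
    """Independent matrix-exponential occupancy of the two-state chain."""
    q = np.array([[-k_oc, k_oc], [k_co, -k_co]])
    p = expm(q * t)
    return p[0, 1]  # long-run closed probability from any start


def test_frozen_chain_stays_put():
    path = simulate_state_path(KineticParams(0.0, 0.0), 100, 0.1, seed=1, start_state=CLOSED)
    assert np.all(path.states == CLOSED)
    assert np.allclose(path.e_mean, 0.6)


def test_symmetric_rates_give_half_occupancy():
    path = simulate_state_path(KineticParams(0.2, 0.2), 100_000, 0.1, seed=2)
    occ = path.frac_closed.mean()
    # frames are correlated with timescale tau = 1/(k_oc+k_co); SE accounts for it
    tau = 1.0 / 0.4
    se = np.sqrt(0.25 * 2 * tau / (100_000 * 0.1))
    assert abs(occ - 0.5) < 3 * se


def test_occupancy_matches_matrix_exponential_oracle():
    k_oc, k_co = 0.3, 0.1
    target = stationary_occupancy_oracle(k_oc, k_co)
    assert abs(target - 0.75) < 1e-9
    path = simulate_state_path(KineticParams(k_oc, k_co), 200_000, 0.1, seed=3)
    occ = path.frac_closed.mean()
    tau = 1.0 / (k_oc + k_co)
    se = np.sqrt(target * (1 - target) * 2 * tau / (200_000 * 0.1))
    assert abs(occ - target) < 3 * se


def test_closed_dwell_time_mean_matches_rate():
    """Mean closed dwell = 1/k_co within 5% over >= 1e4 complete dwells."""
    k_oc, k_co = 2.0, 0.5
    rng = np.random.default_rng(4)
    dwells = []
    while len(dwells) < 10_000:
        path = simulate_state_path(KineticParams(k_oc, k_co), 20_000, 0.1, rng)
        # drop the final (right-censored) dwell
        dwells.extend(d for s, d in path.dwells[:-1] if s == CLOSED)
    mean = np.mean(dwells)
    assert abs(mean - 1.0 / k_co) / (1.0 / k_co) < 0.05


def test_noiseless_static_emission_values():
    kin = KineticParams(0.0, 0.0)
    emi = EmissionParams(i_total=1000, sigma_read=0, background=0,
                         bleach_rate_donor=0, bleach_rate_acceptor=0, n_frames=30)
    tr, gt = simulate_trace(kin, emi, seed=5, start_state=CLOSED)
    assert np.allclose(tr.acceptor, 600.0)
    assert np.allclose(tr.donor, 400.0)


def test_instant_acceptor_bleach_limit():
    kin = KineticParams(0.0, 0.0)
    emi = EmissionParams(i_total=1000, sigma_read=0, background=50,
                         bleach_rate_donor=0, bleach_rate_acceptor=1e9, n_frames=20)
    tr, gt = simulate_trace(kin, emi, seed=6, start_state=CLOSED)
    assert gt.acceptor_bleach_frame == 0
    assert np.allclose(tr.acceptor, 50.0)
    assert np.allclose(tr.donor, 1050.0)


def test_fixed_seed_is_bit_reproducible():
    kin = KineticParams(0.8, 0.4)
    emi = EmissionParams()
    t1, g1 = simulate_trace(kin, emi, seed=7)
    t2, g2 = simulate_trace(kin, emi, seed=7)
    assert np.array_equal(t1.donor, t2.donor)
    assert np.array_equal(t1.acceptor, t2.acceptor)
    assert g1.donor_bleach_frame == g2.donor_bleach_frame
    ts1, _ = simulate_dataset(kin, emi, 10, 0.5, seed=8)
    ts2, _ = simulate_dataset(kin, emi, 10, 0.5, seed=8)
    for a, b in zip(ts1, ts2):
        assert np.array_equal(a.donor, b.donor)


def test_dataset_static_all_closed():
    ts, gt = simulate_dataset(
        KineticParams(0.5, 0.5), EmissionParams(sigma_read=0, bleach_rate_donor=0,
                                                bleach_rate_acceptor=0, n_frames=20),
        10, 0.0, seed=9, p_closed=1.0,
    )
    for tr in ts:
        assert np.allclose(tr.acceptor, 600.0)


def test_dataset_dynamic_occupancy_matches_stationary():
    """300 fully dynamic traces: pooled occupancy ~ 0.5 within 3 SE."""
    kin = KineticParams(0.5, 0.5)
    emi = EmissionParams(n_frames=200, bleach_rate_donor=0, bleach_rate_acceptor=0)
    ts, gt = simulate_dataset(kin, emi, 300, 1.0, seed=10)
    per_trace = np.array([g.states.mean() for g in gt.per_trace])
    se = per_trace.std(ddof=1) / np.sqrt(len(per_trace))
    assert abs(per_trace.mean() - 0.5) < max(3 * se, 0.03)


def test_dataset_dynamic_count_binomial():
    ts, gt = simulate_dataset(
        KineticParams(0.5, 0.5), EmissionParams(n_frames=12), 1000, 0.3, seed=11
    )
    n_dyn = gt.n_dynamic
    sd = np.sqrt(1000 * 0.3 * 0.7)
    assert abs(n_dyn - 300) < 3 * sd


def test_titration_bound_fraction_endpoints():
    kin = KineticParams(0.0, 0.0)
    emi = EmissionParams(n_frames=12, sigma_read=0, bleach_rate_donor=0,
                         bleach_rate_acceptor=0)
    out = simulate_fret_titration(
        600.0, [0.0, 600.0], p_closed_free=1.0, p_closed_bound=0.0,
        kinetics=kin, emission=emi, n_traces=400, seed=12,
    )
    # c=0: identical in law to the free population (all closed here)
    ts0, gt0 = out[0.0]
    assert gt0.p_closed == 1.0
    assert all(np.allclose(tr.acceptor, 600.0) for tr in ts0)
    # c = kd: bound fraction exactly 0.5 -> mixture p_closed exactly 0.5
    ts1, gt1 = out[600.0]
    assert gt1.p_closed == pytest.approx(0.5)
    closed = sum(np.allclose(tr.acceptor, 600.0) for tr in ts1)
    assert abs(closed / 400 - 0.5) < 3 * np.sqrt(0.25 / 400)


def test_anisotropy_titration_endpoints_and_noise():
    curve = simulate_anisotropy_titration(
        120.0, 0.05, 0.15, 10.0, [0.0, 1e7], noise_sd=0.0, seed=13
    )
    assert curve.y[0] == pytest.approx(0.05)
    assert curve.y[1] == pytest.approx(0.15, abs=1e-4)


def test_anisotropy_degenerate_signal_warns():
    with pytest.warns(DegenerateSignalWarning):
        simulate_anisotropy_titration(120.0, 0.05, 0.05, 10.0, [0, 100], 0.0, seed=14)


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(k_oc=-0.1, k_co=0.1),
        dict(k_oc=0.1, k_co=0.1, e_open=0.7, e_closed=0.6),
        dict(k_oc=0.1, k_co=0.1, e_open=-0.1),
    ],
)
def test_invalid_kinetics_rejected(kwargs):
    with pytest.raises(ParameterError):
        KineticParams(**kwargs)


def test_invalid_emission_and_sizes_rejected():
    with pytest.raises(ParameterError):
        EmissionParams(dt=0.0)
    with pytest.raises(ParameterError):
        simulate_state_path(KineticParams(0.1, 0.1), 0, 0.1, seed=1)
    with pytest.raises(ParameterError):
        simulate_dataset(KineticParams(0.1, 0.1), EmissionParams(), 0, 0.5, seed=1)
    with pytest.raises(ParameterError):
        simulate_fret_titration(0.0, [0.0], 0.5, 0.5, KineticParams(1, 1),
                                EmissionParams(), 5, seed=1)
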