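"""Host-parasitoid step maps, conservation identities, calibration."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tgepop import (
    Modes,
    SimParams,
    SimState,
    attack_rate,
    calibrate_attack_coefficient,
    growth_rate,
    make_trajectory,
    simulate_batch,
    simulate_run,
    step_model_a,
    step_model_b,
    tpc_mean,
)
from tgepop.dynamics import (
    equilibrium_state,
    first_extinction_generation,
    parasitism_fraction,
)

PARAMS = SimParams(gamma=0.14, t_p=0.001, K_H=2000.0, h=0.01, d=0.5, k=1.0)


# --------------------------------------------------------------- rates

def test_growth_rate_modes(true_bundle):
    # TGE off: independent of the previous temperature
    r1 = growth_rate(24.0, 19.0, False, true_bundle)
    r2 = growth_rate(24.0, 27.0, False, true_bundle)
    assert r1 == r2 == pytest.approx(tpc_mean(24.0, true_bundle.fly_shared))
    # at the thermal maximum the growth rate is zero
    assert growth_rate(30.0, 24.0, False, true_bundle) == 0.0
    assert growth_rate(30.0, 24.0, True, true_bundle) == 0.0
    # TGE on at a node: exactly the node curve
    r_node = growth_rate(24.0, 23.0, True, true_bundle)
    node = true_bundle.fly_itp.node_params[1]
    assert r_node == pytest.approx(tpc_mean(24.0, node), abs=1e-9)


def test_attack_rate_scaling_and_nodes(true_bundle):
    assert attack_rate(24.0, 24.0, False, true_bundle, 0.0) == 0.0
    for T in (19.0, 24.0, 29.0):
        a = attack_rate(T, 24.0, False, true_bundle, 0.7)
        assert 0.0 < a / 0.7 < 1.0
    # wasp TGE at a node uses exactly the node coefficients
    from tgepop import logistic_eta

    a27 = attack_rate(25.0, 27.0, True, true_bundle, 1.0)
    assert a27 == pytest.approx(
        logistic_eta(25.0, true_bundle.wasp_itp.node_coeffs[2]), abs=1e-9)


# --------------------------------------------------------------- steps

@given(
    N=st.floats(0.0, 1999.0),
    P=st.floats(0.0, 5000.0),
    T=st.floats(16.0, 29.5),
)
@settings(max_examples=100, derandomize=True, deadline=None)
def test_step_conservation_identities(true_bundle, N, P, T):
    s = SimState(N=N, P=P, T_prev=24.0)
    modes = Modes(False, False)
    # Model A: host losses equal wasp recruits (minus immigration)
    r = growth_rate(T, 24.0, False, true_bundle)
    nstar = max(PARAMS.gamma * r * N * (1 - N / PARAMS.K_H), 0.0)
    sa = step_model_a(s, T, PARAMS, modes, true_bundle)
    assert sa.N >= 0 and sa.P >= 0
    assert nstar - sa.N == pytest.approx(sa.P - PARAMS.d, abs=1e-12 * max(nstar, 1))
    # Model B: survivors plus recruits partition the potential hosts
    sb = step_model_b(s, T, PARAMS, modes, true_bundle)
    assert sb.N >= 0 and sb.P >= 0
    assert sb.N + sb.P - PARAMS.d == pytest.approx(nstar, abs=1e-12 * max(nstar, 1))


def test_no_parasitoid_reduces_to_logistic_map(true_bundle):
    p = dataclasses.replace(PARAMS, d=0.0)
    s = SimState(N=800.0, P=0.0, T_prev=24.0)
    out = step_model_a(s, 24.0, p, Modes(False, False), true_bundle)
    r = growth_rate(24.0, 24.0, False, true_bundle)
    assert out.N == pytest.approx(p.gamma * r * 800 * (1 - 800 / p.K_H))
    assert out.P == 0.0
    out_b = step_model_b(s, 24.0, p, Modes(False, False), true_bundle)
    assert out_b.N == pytest.approx(out.N)


def test_zero_attack_passes_hosts_through(true_bundle):
    p = dataclasses.replace(PARAMS, t_p=0.0)
    s = SimState(N=500.0, P=100.0, T_prev=24.0)
    out = step_model_a(s, 24.0, p, Modes(False, False), true_bundle)
    r = growth_rate(24.0, 24.0, False, true_bundle)
    assert out.N == pytest.approx(p.gamma * r * 500 * (1 - 500 / p.K_H))
    assert out.P == p.d


def test_model_b_large_k_matches_exponential_escape(true_bundle):
    # (1 + x/k)^(-k) -> exp(-x): the Nicholson-Bailey escape limit
    p = dataclasses.replace(PARAMS, k=1e6)
    s = SimState(N=900.0, P=300.0, T_prev=24.0)
    out = step_model_b(s, 24.0, p, Modes(False, False), true_bundle)
    r = growth_rate(24.0, 24.0, False, true_bundle)
    alpha = attack_rate(24.0, 24.0, False, true_bundle, p.t_p)
    nstar = p.gamma * r * 900 * (1 - 900 / p.K_H)
    expected = nstar * np.exp(-alpha * 300 / (1 + alpha * p.h * nstar))
    assert out.N == pytest.approx(expected, rel=1e-4)


def test_type_ii_per_parasitoid_kill_saturates_at_inverse_h(true_bundle):
    # as N* grows the per-wasp kill count approaches 1/h = 100
    p = dataclasses.replace(PARAMS, K_H=1e12, t_p=1.0)
    big_n = 5e9  # N* will be enormous
    s = SimState(N=big_n, P=1.0, T_prev=24.0)
    r = growth_rate(24.0, 24.0, False, true_bundle)
    nstar = p.gamma * r * big_n * (1 - big_n / p.K_H)
    out = step_model_a(s, 24.0, p, Modes(False, False), true_bundle)
    kills = nstar - out.N
    assert kills == pytest.approx(1.0 / p.h, rel=1e-3)


# ---------------------------------------------------------- simulation

def test_immediate_collapse_when_growth_zero(true_bundle):
    p = dataclasses.replace(PARAMS, gamma=0.0)
    traj = make_trajectory(sigma=0.0, seed=0)
    res = simulate_run(traj, p, "A", Modes(False, False), true_bundle, 800.0, 10.0)
    assert res.extinction_generation == 1 and not res.censored


def test_extinction_generation_definition():
    series = [50.0, 40.0, 30.0, 20.0, 10.0, 5.0, 0.5, 0.2]
    assert first_extinction_generation(series, 1.0) == 7
    assert first_extinction_generation([5.0, 4.0], 1.0) is None


@pytest.fixture(scope="module")
def calibrated(true_bundle):
    out = {}
    for model in ("A", "B"):
        p0 = SimParams(gamma=3.2 / tpc_mean(24.0, true_bundle.fly_shared),
                       t_p=0.0)
        tp = calibrate_attack_coefficient(p0, true_bundle, model=model)
        p = dataclasses.replace(p0, t_p=tp)
        eq = equilibrium_state(p, true_bundle, model=model)
        out[model] = (p, eq)
    return out


class TestCalibratedSystem:
    @pytest.mark.parametrize("model", ["A", "B"])
    def test_calibration_reaches_parasitism_band(self, calibrated, true_bundle, model):
        p, eq = calibrated[model]
        f = parasitism_fraction(np.full(500, 24.0), p, model,
                                Modes(False, False), true_bundle, *eq)
        assert 0.45 <= f <= 0.55

    @pytest.mark.parametrize("model", ["A", "B"])
    def test_persistence_at_constant_temperature(self, calibrated, true_bundle, model):
        # no warming: the calibrated system survives 2500 generations with
        # the host bounded in (0, K_H]
        p, eq = calibrated[model]
        temps = np.full((1, 2500), 24.0)
        ext, cens, Ns, _ = simulate_batch(temps, p, model,
                                          Modes(False, False), true_bundle, *eq)
        assert cens[0]
        assert Ns.min() > 0 and Ns.max() <= p.K_H

    @pytest.mark.parametrize("model", ["A", "B"])
    def test_zero_attack_gives_zero_parasitism(self, calibrated, true_bundle, model):
        p, eq = calibrated[model]
        p0 = dataclasses.replace(p, t_p=0.0)
        f = parasitism_fraction(np.full(300, 24.0), p0, model,
                                Modes(False, False), true_bundle, *eq)
        assert f == 0.0

    def test_faster_warming_never_delays_extinction(self, calibrated, true_bundle):
        # same 5 C of warming compressed into a shorter ramp: the median
        # extinction generation over paired seeds cannot increase
        p, eq = calibrated["B"]
        med = {}
        for n_ramp in (2000, 1000):
            temps = np.stack([
                make_trajectory(rho=0.8, sigma=1.0, n_ramp=n_ramp, seed=s).temps
                for s in range(20)
            ])
            ext, cens, _, _ = simulate_batch(temps, p, "B",
                                             Modes(False, False), true_bundle, *eq)
            assert not cens.any()
            med[n_ramp] = np.median(ext)
        assert med[1000] <= med[2000]
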