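"""Thermal performance curve and negative-binomial fitting machinery."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tgepop import (
    FlyDesign,
    FlyParams,
    TPCParams,
    fit_fly_variant,
    fly_model_table,
    gen_fly_experiment,
    nb_loglik,
    tpc_mean,
)
from tgepop.errors import ValidationError


def nb_logpmf_oracle(k, mu, theta):
    """Independent NB(mean mu, size theta) log-pmf via the gamma-function
    formula, coded separately from the likelihood implementation."""
    return (
        math.lgamma(k + theta)
        - math.lgamma(theta)
        - math.lgamma(k + 1)
        + theta * math.log(theta / (theta + mu))
        + k * math.log(mu / (theta + mu))
    )


@pytest.mark.parametrize("topt, rmax, a", [(25.5, 22.0, 6.0), (27.0, 38.0, 7.0), (20.0, 5.0, 2.0)])
def test_tpc_closed_form_identities(topt, rmax, a):
    p = TPCParams(topt=topt, rmax=rmax, a=a)
    assert tpc_mean(topt, p) == pytest.approx(rmax, abs=1e-12)
    assert tpc_mean(p.ctmax, p) == pytest.approx(0.0, abs=1e-12)
    assert tpc_mean(topt - 2 * a, p) == pytest.approx(rmax * math.exp(-1), abs=1e-12)
    mid = (topt + p.ctmax) / 2
    assert tpc_mean(mid, p) == pytest.approx(0.75 * rmax, abs=1e-12)


@given(st.floats(16.0, 29.0), st.floats(1.0, 50.0), st.floats(1.0, 10.0))
@settings(max_examples=60, derandomize=True, deadline=None)
def test_tpc_continuous_at_topt_and_nonnegative(topt, rmax, a):
    p = TPCParams(topt=topt, rmax=rmax, a=a)
    eps = 1e-9
    below = tpc_mean(topt - eps, p)
    above = tpc_mean(topt + eps, p)
    assert below == pytest.approx(above, abs=1e-5 * rmax)
    temps = np.linspace(0, 40, 401)
    assert (tpc_mean(temps, p) >= 0).all()
    assert (tpc_mean(temps[temps >= p.ctmax], p) == 0).all()


def test_nb_loglik_zero_count_closed_form():
    p = TPCParams(topt=23.0, rmax=10.0, a=5.0)
    data = pd.DataFrame({"g0_temp": [23.0], "g1_temp": [23.0], "count": [0]})
    theta = 1.7
    mu = tpc_mean(23.0, p)
    expected = theta * math.log(theta / (theta + mu))
    got = nb_loglik(data, FlyParams(by_g0={23.0: p}, theta=theta))
    assert got == pytest.approx(expected, abs=1e-12)


def test_nb_loglik_matches_oracle_and_is_additive(rng):
    params = FlyParams(
        by_g0={
            19.0: TPCParams(24.0, 20.0, 5.0),
            23.0: TPCParams(26.0, 30.0, 6.0),
            27.0: TPCParams(25.0, 10.0, 7.0),
        },
        theta=2.3,
    )
    g0 = rng.choice([19.0, 23.0, 27.0], size=20)
    g1 = rng.choice([19.0, 21.0, 23.0, 25.0, 27.0], size=20)
    counts = rng.integers(0, 80, size=20)
    data = pd.DataFrame({"g0_temp": g0, "g1_temp": g1, "count": counts})
    expected = sum(
        nb_logpmf_oracle(int(k), tpc_mean(t1, params.by_g0[t0]), params.theta)
        for t0, t1, k in zip(g0, g1, counts)
    )
    got = nb_loglik(data, params)
    assert got == pytest.approx(expected, abs=1e-10)
    # additivity over records
    parts = sum(nb_loglik(data.iloc[[i]], params) for i in range(len(data)))
    assert got == pytest.approx(parts, abs=1e-9)


def test_poisson_variant_uses_poisson_pmf(rng):
    p = TPCParams(24.0, 15.0, 5.0)
    counts = rng.integers(0, 40, size=10)
    data = pd.DataFrame({"g0_temp": 19.0, "g1_temp": 21.0, "count": counts})
    mu = tpc_mean(21.0, p)
    expected = sum(
        -mu + k * math.log(mu) - math.lgamma(k + 1) for k in counts
    )
    got = nb_loglik(data, FlyParams(by_g0={19.0: p}, theta=None))
    assert got == pytest.approx(expected, abs=1e-10)


def test_mean_floor_warns_when_data_beyond_ctmax():
    p = TPCParams(24.0, 15.0, 5.0)
    data = pd.DataFrame({"g0_temp": [19.0], "g1_temp": [31.0], "count": [0]})
    with pytest.warns(RuntimeWarning, match="floored"):
        ll = nb_loglik(data, FlyParams(by_g0={19.0: p}, theta=1.0))
    assert np.isfinite(ll)


@pytest.fixture(scope="module")
def fits(fly_data):
    return {
        v: fit_fly_variant(fly_data, v, n_starts=10, seed=1)
        for v in ("1b", "1c", "1d")
    }


class TestFitting:
    def test_nested_variants_increase_loglik(self, fits):
        assert fits["1d"].loglik >= fits["1c"].loglik - 1e-6
        assert fits["1c"].loglik >= fits["1b"].loglik - 1e-6

    def test_parameter_counts_and_aic_identity(self, fits):
        expected_n = {"1b": 4, "1c": 7, "1d": 10}
        for v, fit in fits.items():
            assert fit.n_params == expected_n[v]
            assert fit.aic == pytest.approx(2 * fit.n_params - 2 * fit.loglik, abs=1e-9)

    def test_shared_variant_ignores_g0(self, fits):
        vals = list(fits["1b"].params.by_g0.values())
        for p in vals[1:]:
            assert p.topt == vals[0].topt
            assert p.rmax == vals[0].rmax

    def test_empty_or_degenerate_data_rejected(self):
        with pytest.raises(ValidationError):
            fit_fly_variant(pd.DataFrame(columns=["g0_temp", "g1_temp", "count"]), "1b")
        one_g1 = pd.DataFrame(
            {"g0_temp": [19.0] * 4, "g1_temp": [23.0] * 4, "count": [1, 2, 3, 4]}
        )
        with pytest.raises(ValidationError):
            fit_fly_variant(one_g1, "1d")


def test_model_table_delta_aic_properties(fly_data):
    table = fly_model_table(fly_data, variants=("1a", "1b", "1d"), n_starts=8, seed=2)
    assert (table["delta_aic"] == 0).sum() == 1
    best = table.loc[table["delta_aic"].idxmin()]
    for _, row in table.iterrows():
        expected = (
            2 * (row["n_params"] - best["n_params"])
            - 2 * (row["loglik"] - best["loglik"])
        )
        assert row["delta_aic"] == pytest.approx(expected, abs=1e-9)
    # overdispersed counts: Poisson variant must lose badly
    assert table.set_index("variant").loc["1a", "delta_aic"] > 100
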