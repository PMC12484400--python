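"""Binomial logit models of the wasp share of emergences."""

import math

import numpy as np
import pandas as pd
import pytest

from tgepop import (
    WaspDesign,
    WaspLogitCoeffs,
    binom_loglik,
    fit_wasp_variant,
    gen_wasp_experiment,
    logistic_eta,
    total_count_independence,
    wasp_model_table,
)
from tgepop.errors import ValidationError
from tgepop.synth import default_wasp_true_coeffs


def binom_logpmf_oracle(k, n, p):
    return (
        math.lgamma(n + 1)
        - math.lgamma(k + 1)
        - math.lgamma(n - k + 1)
        + k * math.log(p)
        + (n - k) * math.log(1 - p)
    )


def test_logistic_eta_matches_direct_inverse_logit(rng):
    for _ in range(50):
        icpt = rng.normal(scale=3)
        slope = rng.normal(scale=0.3)
        T = rng.uniform(15, 30)
        direct = 1.0 / (1.0 + math.exp(-(icpt + slope * T)))
        got = logistic_eta(T, WaspLogitCoeffs(icpt, slope))
        assert got == pytest.approx(direct, abs=1e-12)
        assert 0.0 < got < 1.0


def test_logistic_eta_monotone_in_temperature():
    c = WaspLogitCoeffs(-2.0, 0.3)
    temps = np.linspace(15, 30, 50)
    vals = logistic_eta(temps, c)
    assert (np.diff(vals) > 0).all()


def test_binom_loglik_closed_form_and_oracle(rng):
    # all-wasp vial at p = 1/2
    data = pd.DataFrame(
        {"g0_temp": [19.0], "g1_temp": [0.0], "wasp_count": [7], "fly_count": [0]}
    )
    got = binom_loglik(data, WaspLogitCoeffs(0.0, 0.0))
    assert got == pytest.approx(7 * math.log(0.5), abs=1e-12)

    coeffs = {
        19.0: WaspLogitCoeffs(2.0, -0.1),
        23.0: WaspLogitCoeffs(0.0, 0.02),
        27.0: WaspLogitCoeffs(-3.0, 0.15),
    }
    g0 = rng.choice([19.0, 23.0, 27.0], 20)
    g1 = rng.choice([19.0, 21.0, 23.0, 25.0, 27.0], 20)
    total = rng.integers(1, 120, 20)
    wasp = rng.binomial(total, 0.5)
    data = pd.DataFrame(
        {"g0_temp": g0, "g1_temp": g1, "wasp_count": wasp, "fly_count": total - wasp}
    )
    expected = sum(
        binom_logpmf_oracle(int(w), int(n), logistic_eta(t1, coeffs[t0]))
        for t0, t1, w, n in zip(g0, g1, wasp, total)
    )
    assert binom_loglik(data, coeffs) == pytest.approx(expected, abs=1e-10)
    parts = sum(binom_loglik(data.iloc[[i]], coeffs) for i in range(len(data)))
    assert binom_loglik(data, coeffs) == pytest.approx(parts, abs=1e-9)


def test_zero_total_vials_contribute_nothing():
    data = pd.DataFrame(
        {"g0_temp": [19.0, 19.0], "g1_temp": [21.0, 21.0],
         "wasp_count": [0, 5], "fly_count": [0, 5]}
    )
    only_second = binom_loglik(data.iloc[[1]], WaspLogitCoeffs(0.0, 0.0))
    assert binom_loglik(data, WaspLogitCoeffs(0.0, 0.0)) == pytest.approx(only_second)


@pytest.fixture(scope="module")
def fits(wasp_data):
    return {v: fit_wasp_variant(wasp_data, v) for v in ("2a", "2b", "2c", "2d")}


class TestWaspFits:
    def test_nesting_chain(self, fits):
        assert fits["2d"].loglik >= fits["2c"].loglik - 1e-6
        assert fits["2c"].loglik >= fits["2b"].loglik - 1e-6
        assert fits["2b"].loglik >= fits["2a"].loglik - 1e-6

    def test_parameter_counts(self, fits):
        assert [fits[v].n_params for v in ("2a", "2b", "2c", "2d")] == [2, 3, 4, 6]

    def test_2d_equals_sum_of_independent_per_g0_fits(self, wasp_data, fits):
        total = 0.0
        for g0, grp in wasp_data.groupby("g0_temp"):
            sub = fit_wasp_variant(grp, "2a")
            total += sub.loglik
        assert fits["2d"].loglik == pytest.approx(total, abs=1e-6)

    def test_2d_recovers_generating_coefficients(self, fits):
        # large-ish n per group: estimates close to truth on the logit scale
        truth = default_wasp_true_coeffs()
        for g0, c in fits["2d"].coeffs_by_g0.items():
            assert c.intercept == pytest.approx(truth[g0].intercept, abs=1.0)
            assert c.slope == pytest.approx(truth[g0].slope, abs=0.05)

    def test_model_table_selects_g0_structure(self, wasp_data):
        table = wasp_model_table(wasp_data)
        assert (table["delta_aic"] == 0).sum() == 1
        assert table.iloc[0]["variant"] == "2d"  # true coeffs differ per G0
        aic = table.set_index("variant")["aic"]
        assert aic["2d"] < aic["2c"] < aic["2b"] < aic["2a"]


def test_total_count_independence_matches_statsmodels_shape(wasp_data):
    F, (df1, df2), p = total_count_independence(wasp_data)
    assert df1 == 1
    assert df2 == len(wasp_data) - 2
    assert F >= 0 and 0 <= p <= 1


def test_total_count_independence_type_i_error_rate(rng):
    # totals independent of G1: ~5% rejections at alpha = 0.05
    g1 = np.tile([19.0, 21.0, 23.0, 25.0, 27.0], 12)
    rejections = 0
    n_rep = 400
    for _ in range(n_rep):
        total = rng.poisson(90.0, size=g1.size)
        data = pd.DataFrame(
            {"g0_temp": 19.0, "g1_temp": g1,
             "wasp_count": total, "fly_count": 0}
        )
        _, _, p = total_count_independence(data)
        rejections += p < 0.05
    rate = rejections / n_rep
    assert 0.02 <= rate <= 0.09  # ~3 SE band around 0.05


def test_degenerate_predictor_rejected():
    data = pd.DataFrame(
        {"g0_temp": [19.0] * 5, "g1_temp": [23.0] * 5,
         "wasp_count": [1] * 5, "fly_count": [2] * 5}
    )
    with pytest.raises(ValidationError):
        total_count_independence(data)
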