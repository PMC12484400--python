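"""Shared fixtures: synthetic datasets and a known-truth fit bundle."""

import numpy as np
import pytest

from tgepop import (
    FitBundle,
    FlyDesign,
    TPCParams,
    WaspDesign,
    WaspLogitCoeffs,
    gen_fly_experiment,
    gen_wasp_experiment,
)
from tgepop.interpolate import InterpolatedFlyTPC, InterpolatedWaspEta
from tgepop.synth import default_fly_true_params, default_wasp_true_coeffs


@pytest.fixture(scope="session")
def fly_data():
    return gen_fly_experiment(FlyDesign(seed=7))


@pytest.fixture(scope="session")
def wasp_data():
    return gen_wasp_experiment(WaspDesign(seed=11))


@pytest.fixture(scope="session")
def true_bundle():
    """Fit bundle built directly from the generator's true parameters.

    Lets dynamics and experiment tests run without any fitting: the node
    curves are the synthetic truth, and the shared (G0-blind) curve / logit
    stand in for what a pooled fit would give.
    """
    nodes = default_fly_true_params()
    itp = InterpolatedFlyTPC(
        node_temps=[19.0, 23.0, 27.0],
        node_params=[nodes[19.0], nodes[23.0], nodes[27.0]],
    )
    wc = default_wasp_true_coeffs()
    witp = InterpolatedWaspEta(
        node_temps=[19.0, 23.0, 27.0],
        node_coeffs=[wc[19.0], wc[23.0], wc[27.0]],
    )
    return FitBundle(
        fly_shared=TPCParams(topt=26.5, rmax=24.0, a=7.0, theta=1.5),
        fly_itp=itp,
        wasp_shared=WaspLogitCoeffs(-0.385, 0.049),
        wasp_itp=witp,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20250921)
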