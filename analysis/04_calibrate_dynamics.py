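"""Calibrate the host-parasitoid simulators at the pre-warming baseline.

Sets gamma so the host growth multiplier at 24 C is 3.2, tunes the wasp
attack coefficient t_p until ~50% of potential hosts are parasitised at
equilibrium, and records the coexistence state each model starts from.
"""

import dataclasses
import json

import numpy as np

from tgepop import SimParams, tpc_mean
from tgepop.dynamics import (
    Modes,
    calibrate_attack_coefficient,
    equilibrium_state,
    parasitism_fraction,
)
from tgepop.io import bundle_from_fits, fly_fit_from_dict, wasp_fit_from_dict

fly_fits = json.loads(open("results/tables/fly_fits.json").read())
wasp_fits = json.loads(open("results/tables/wasp_fits.json").read())
bundle = bundle_from_fits(
    fly_fit_from_dict(fly_fits["1b"]), fly_fit_from_dict(fly_fits["1d"]),
    wasp_fit_from_dict(wasp_fits["2a"]), wasp_fit_from_dict(wasp_fits["2d"]))

GROWTH_TARGET = 3.2
gamma = GROWTH_TARGET / tpc_mean(24.0, bundle.fly_shared)
out = {}
for model in ("A", "B"):
    p0 = SimParams(gamma=gamma, t_p=0.0)
    tp = calibrate_attack_coefficient(p0, bundle, model=model)
    p = dataclasses.replace(p0, t_p=tp)
    N0, P0 = equilibrium_state(p, bundle, model=model)
    f = parasitism_fraction(np.full(500, 24.0), p, model, Modes(), bundle, N0, P0)
    out[model] = {"gamma": gamma, "t_p": tp, "N0": N0, "P0": P0,
                  "burnin_parasitism": f}
    print(f"model {model}: gamma={gamma:.4f} t_p={tp:.5f} "
          f"equilibrium N={N0:.0f} P={P0:.0f} parasitism={f:.3f}")
json.dump(out, open("results/calibration.json", "w"), indent=2)
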