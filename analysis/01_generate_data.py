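"""Generate the two synthetic factorial experiments used throughout.

Writes vial-level CSVs (one row per vial) for the fly reproduction
experiment (3 G0 x 5 G1 x 40 vials) and the wasp parasitism experiment
(3 x 5 x 18 vials) under results/data/.
"""

import numpy as np
from tgepop import FlyDesign, WaspDesign, gen_fly_experiment, gen_wasp_experiment
from tgepop import io as tio

MASTER_SEED = 1
ss = np.random.SeedSequence(MASTER_SEED)
fly_seed, wasp_seed = (int(s % (2**31 - 1)) for s in ss.generate_state(2, dtype=np.uint64))

fly = gen_fly_experiment(FlyDesign(seed=fly_seed))
wasp = gen_wasp_experiment(WaspDesign(seed=wasp_seed))
tio.write_vial_csv(fly, "results/data/fly.csv")
tio.write_vial_csv(wasp, "results/data/wasp.csv")
print(f"fly experiment: {len(fly)} vials, {fly['count'].sum()} emergences")
print(f"wasp experiment: {len(wasp)} vials, "
      f"{wasp['wasp_count'].sum()} wasps / {wasp['fly_count'].sum()} flies")
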