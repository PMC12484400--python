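"""Analyse the extinction grids: geometric means per scenario and the
Type III mixed-model tests of the transgenerational / autocorrelation
interaction on log time-to-extinction."""

import pandas as pd

from tgepop import summarize_extinctions
from tgepop.lmm import fit_extinction_lmm

for model in ("A", "B"):
    grid = pd.read_csv(f"results/extinctions_model{model}.csv")
    summary = summarize_extinctions(grid)
    summary.to_csv(f"results/summary_model{model}.csv", index=False)
    anova = fit_extinction_lmm(grid)
    anova.to_csv(f"results/anova_model{model}.csv", index=False)
    print(f"== model {model}")
    print(summary[["rho", "scenario", "geometric_mean", "median"]]
          .to_string(index=False))
    three = anova.set_index("term").loc["autocorr:fly_tge:wasp_tge"]
    print(f"three-way interaction: F(1, {three.df_den:.0f}) = {three.F:.3f}, "
          f"p = {three.p:.3g}\n")
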