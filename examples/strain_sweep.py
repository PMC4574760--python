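"""Strain dependence of the differentiation pattern.

Sweeps the applied strain amplitude from 0 to 15% and prints, for each
strain, the day-21 stem/terminal fractions and the qualitative pattern
(static-like: stem cells still growing at day 21, no terminal cells;
dynamic-like: stem maximum at day 3 and MHC+ cells present).  Then
bisects for the critical strains at which each classifier flips.
"""

import numpy as np

import myokinetics as mk
from myokinetics.engine import sweep_frame

cfg = mk.default_config().with_horizon(40.0)
eps_grid = [round(x, 3) for x in np.arange(0.0, 0.1501, 0.01)]
rows = mk.strain_sweep(cfg, eps_grid)

df = sweep_frame(rows)
print(df[["epsilon", "frac_stem_day21", "frac_term_day21",
          "day_n0_max", "day_n3_threshold", "pattern"]].round(3).to_string(index=False))

crit0 = mk.critical_strain(cfg.with_horizon(21.0), 0.0, 0.05, "n0max_switch")
crit4 = mk.critical_strain(cfg.with_horizon(21.0), 0.0, 0.06, "n4_appearance")
print(f"\nstem-cell maximum leaves day 21 above  {100 * crit0:.2f}% strain")
print(f"terminal cells present at day 21 above {100 * crit4:.2f}% strain")
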