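"""Study-level summaries from the packaged LT50 reference table.

Loads the 48-cell table of published semi-lethal temperatures and prints
the two headline statistics: the moisture-content extreme difference and
the freezing-duration effect for pine.
"""

import frosteis as fe

table = fe.table2_dataframe()

diff = fe.mc_extreme_difference(table, "Pi", "Slow", 1.0)
print(f"pine, slow cooling, 1 h: LT50 gap between 200% and 10% moisture "
      f"= {diff:.2f} degC")
# wetter sapwood tolerates ~20 degC deeper frost before half-lethal injury

for species in ("Pi", "Po"):
    eff = fe.duration_effect(table, species)
    print(f"\n{species}: LT50 change from 0.5 h to 1 h freezing, "
          f"{len(eff.per_condition)} conditions")
    print(f"  formula: {eff.formula}")
    print(f"  mean = {eff.mean_pct:.2f}%   max = {eff.max_pct:.2f}%")
# positive percentages: the longer freeze is lethal at warmer temperatures
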