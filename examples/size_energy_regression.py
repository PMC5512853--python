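"""Regress each energy component on interface size, per functional group.

Generates a survey-sized synthetic table (278 complexes in the standard
six-function composition) whose vdW channel is planted at population
R^2 = 0.87, then fits |E| ~ interface_size per group and prints r^2 with
the ANOVA p-value.  High vdW r^2 in every group with weaker, group-specific
H-bond/electrostatic fits is the signature pattern this package measures.
"""

from ppiface import TableSpec, build_energy_table
from ppiface.group_stats import regression_table

df = build_energy_table(TableSpec(seed=11))
df["all"] = "all"

for grouping in ("all", "rollup"):
    table = regression_table(df, grouping)
    print(f"\n=== r^2 by {grouping} ===")
    cols = ["group", "n"] + [c for c in table.columns if c.startswith("r2_")]
    print(table[cols].to_string(index=False))

print("\nr2_vdw ~ 0.87 everywhere: vdW energy tracks interface size; "
      "r2_elec is small: electrostatics is not proportional to size.")
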