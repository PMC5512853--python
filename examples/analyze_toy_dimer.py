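"""Analyze one synthetic two-chain complex end to end.

Builds a toy dimer with 3 planted hydrogen bonds and 1 salt bridge, runs
the full pipeline (dASA interface, contact detection, energy decomposition,
polarity class) and prints the per-complex summary.  The percentages say
how much each interaction channel contributes to the favourable binding
pseudo-energy; they always sum to 100.
"""

import json
import tempfile
from pathlib import Path

from ppiface import DimerSpec, build_toy_dimer, run_complex

spec = DimerSpec(n_residues=10, n_planted_hbonds=3, n_planted_saltbridges=1,
                 interface_contact_fraction=0.6, polarity_target="A", seed=7)

with tempfile.TemporaryDirectory() as tmp:
    pdb_path = Path(tmp) / "TOY1.pdb"
    pdb_path.write_text(build_toy_dimer(spec))
    result = run_complex(pdb_path, ("A", "B"))

print(json.dumps(result.row(), indent=2, default=str))
print(f"\ninterface residues (both chains): {result.interface.interface_size}"
      f" | buried area: {result.interface.interface_area:.1f} A^2"
      f" | polarity class: {result.polarity_class}")
print("planted 3 H-bonds and 1 salt bridge -> detected "
      f"{result.row()['n_hbond']} H-bonds and {result.row()['n_elec']} "
      "charged-atom pairs (2 per salt bridge: NZ against each carboxylate O)")
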