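"""Distance-based detection and pseudo-energy scoring of inter-chain
non-covalent interactions.

Three channels, each with its own distance cutoff:

* **Hydrogen bonds** (default 3.5 A): heavy-atom donor/acceptor N,O pairs
  across the interface.  Energy is a linear well
  ``E(d) = E0 * (1 - (d - d_opt)/(cutoff - d_opt))`` clamped to ``[E0, 0]``
  with ``d_opt = 2.8 A`` and ``E0 = -2 kcal/mol``.
* **Electrostatics** (default 6.0 A): pairs of formally charged atoms,
  screened Coulomb with a distance-dependent dielectric ``eps(d) = 4d``:
  ``E = 332.0637 q_i q_j / (4 d^2)`` kcal/mol.  Repulsive (positive) terms
  are computed and retained.
* **van der Waals** (default 8.0 A): Lennard-Jones 6-12 over all inter-chain
  heavy-atom pairs, ``E = eps_ij [(rmin_ij/d)^12 - 2 (rmin_ij/d)^6]`` with
  Lorentz-Berthelot combining (``rmin_ij = r_i + r_j``,
  ``eps_ij = sqrt(eps_i eps_j)``); clashes below ``0.7 rmin_ij`` evaluate at
  the clamp distance.

Salt bridges (charged N/O pairs inside both the H-bond and electrostatic
cutoffs) score in BOTH channels by design; see the energy-decomposition
docs for how that choice propagates.

Pair search uses a k-d tree; ``method="brute"`` switches to the exhaustive
O(n^2) scan, which must (and in the tests does) yield identical records.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .structure_model import Atom, DimerComplex

COULOMB_CONSTANT = 332.0637       # kcal/mol * A / e^2
DEFAULT_HBOND_CUTOFF = 3.5        # A
DEFAULT_ELEC_CUTOFF = 6.0         # A
DEFAULT_VDW_CUTOFF = 8.0          # A
HBOND_OPTIMAL = 2.8               # A
HBOND_E0 = -2.0                   # kcal/mol
CLASH_FRACTION = 0.7              # of rmin_ij


@dataclass
class InteractionRecord:
    kind: str              # "hbond" | "electrostatic" | "vdw"
    atom_a: Atom           # on chain A
    atom_b: Atom           # on chain B
    distance: float        # A
    energy: float          # kcal/mol, negative = favourable

    def key(self) -> tuple:
        # unordered atom-pair identity for symmetry checks
        ka = (self.atom_a.chain_id, self.atom_a.residue_seq, self.atom_a.name)
        kb = (self.atom_b.chain_id, self.atom_b.residue_seq, self.atom_b.name)
        return (self.kind, *sorted((ka, kb)))


def _cross_chain_pairs(atoms_a: list[Atom], atoms_b: list[Atom],
                       cutoff: float, method: str) -> list[tuple[int, int, float]]:
    """All (i, j, distance) pairs with one atom per chain and d <= cutoff."""
    if not atoms_a or not atoms_b:
        return []
    ca = np.stack([a.coord for a in atoms_a])
    cb = np.stack([b.coord for b in atoms_b])
    if method == "grid":
        pairs = cKDTree(ca).query_ball_tree(cKDTree(cb), cutoff)
        out = []
        for i, js in enumerate(pairs):
            for j in js:
                d = float(np.linalg.norm(ca[i] - cb[j]))
                if d <= cutoff:
                    out.append((i, j, d))
        return out
    if method == "brute":
        # candidate selection may differ in rounding from the final per-pair
        # distance, so pad the matrix test and recompute each distance with
        # the same expression the grid path uses (bitwise-identical output)
        dmat = np.linalg.norm(ca[:, None, :] - cb[None, :, :], axis=2)
        out = []
        for i, j in np.argwhere(dmat <= cutoff + 1e-9):
            d = float(np.linalg.norm(ca[i] - cb[j]))
            if d <= cutoff:
                out.append((int(i), int(j), d))
        return out
    raise ValueError(f"unknown pair-search method {method!r}")


def _sorted_records(records: list[InteractionRecord]) -> list[InteractionRecord]:
    return sorted(records, key=lambda r: r.key())


def hbond_energy(distance: float, cutoff: float = DEFAULT_HBOND_CUTOFF,
                 d_opt: float = HBOND_OPTIMAL, e0: float = HBOND_E0) -> float:
    """Linear H-bond well: E0 at the optimum, 0 at the cutoff, clamped."""
    frac = 1.0 - (distance - d_opt) / (cutoff - d_opt)
    return float(np.clip(e0 * frac, e0, 0.0))


def detect_hbonds(complex_: DimerComplex, cutoff: float = DEFAULT_HBOND_CUTOFF,
                  d_opt: float = HBOND_OPTIMAL, e0: float = HBOND_E0,
                  method: str = "grid") -> list[InteractionRecord]:
    """Inter-chain donor-acceptor N/O pairs within the cutoff.

    A pair qualifies if one side can donate (class donor/both) and the other
    can accept (class acceptor/both); geometry is heavy-atom only.
    """
    donors_ok = ("donor", "both")
    acceptors_ok = ("acceptor", "both")
    atoms_a = [a for a in complex_.atoms(complex_.chain_a_id)
               if a.hbond_class != "none" and a.element in ("N", "O")]
    atoms_b = [b for b in complex_.atoms(complex_.chain_b_id)
               if b.hbond_class != "none" and b.element in ("N", "O")]
    records = []
    for i, j, d in _cross_chain_pairs(atoms_a, atoms_b, cutoff, method):
        a, b = atoms_a[i], atoms_b[j]
        ab = a.hbond_class in donors_ok and b.hbond_class in acceptors_ok
        ba = b.hbond_class in donors_ok and a.hbond_class in acceptors_ok
        if ab or ba:
            records.append(InteractionRecord(
                "hbond", a, b, d, hbond_energy(d, cutoff, d_opt, e0)))
    return _sorted_records(records)


def detect_electrostatics(complex_: DimerComplex,
                          cutoff: float = DEFAULT_ELEC_CUTOFF,
                          method: str = "grid") -> list[InteractionRecord]:
    """Screened Coulomb terms between formally charged atoms across chains.

    Repulsive (like-charge) terms are retained in the records; the
    decomposition stage applies the net-repulsion caveat.
    """
    atoms_a = [a for a in complex_.atoms(complex_.chain_a_id) if a.charge != 0.0]
    atoms_b = [b for b in complex_.atoms(complex_.chain_b_id) if b.charge != 0.0]
    records = []
    for i, j, d in _cross_chain_pairs(atoms_a, atoms_b, cutoff, method):
        a, b = atoms_a[i], atoms_b[j]
        d_eff = max(d, 1e-3)  # guard exact overlap
        energy = COULOMB_CONSTANT * a.charge * b.charge / (4.0 * d_eff * d_eff)
        records.append(InteractionRecord("electrostatic", a, b, d, energy))
    return _sorted_records(records)


def lj_energy(distance: float, rmin: float, eps: float) -> float:
    """6-12 Lennard-Jones with the clash clamp at 0.7*rmin."""
    d = max(distance, CLASH_FRACTION * rmin)
    s6 = (rmin / d) ** 6
    return eps * (s6 * s6 - 2.0 * s6)


def compute_vdw(complex_: DimerComplex, cutoff: float = DEFAULT_VDW_CUTOFF,
                method: str = "grid") -> list[InteractionRecord]:
    """Lennard-Jones terms for every inter-chain heavy-atom pair in range."""
    atoms_a = [a for a in complex_.atoms(complex_.chain_a_id) if a.element != "H"]
    atoms_b = [b for b in complex_.atoms(complex_.chain_b_id) if b.element != "H"]
    records = []
    for i, j, d in _cross_chain_pairs(atoms_a, atoms_b, cutoff, method):
        a, b = atoms_a[i], atoms_b[j]
        rmin = a.vdw_radius + b.vdw_radius
        eps = float(np.sqrt(a.lj_well_depth * b.lj_well_depth))
        records.append(InteractionRecord("vdw", a, b, d, lj_energy(d, rmin, eps)))
    return _sorted_records(records)


def detect_all(complex_: DimerComplex,
               hbond_cutoff: float = DEFAULT_HBOND_CUTOFF,
               elec_cutoff: float = DEFAULT_ELEC_CUTOFF,
               vdw_cutoff: float = DEFAULT_VDW_CUTOFF,
               method: str = "grid") -> list[InteractionRecord]:
    return (detect_hbonds(complex_, hbond_cutoff, method=method)
            + detect_electrostatics(complex_, elec_cutoff, method=method)
            + compute_vdw(complex_, vdw_cutoff, method=method))


def interactions_table(records: list[InteractionRecord]) -> "pandas.DataFrame":  # noqa: F821
    """TSV-ready per-contact table."""
    import pandas as pd

    rows = [{
        "kind": r.kind,
        "chainA_res": f"{r.atom_a.residue_name}{r.atom_a.residue_seq}",
        "atomA": r.atom_a.name,
        "chainB_res": f"{r.atom_b.residue_name}{r.atom_b.residue_seq}",
        "atomB": r.atom_b.name,
        "distance": round(r.distance, 3),
        "energy": round(r.energy, 4),
    } for r in records]
    return pd.DataFrame(rows)
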