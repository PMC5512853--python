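"""Solvent accessible surface area and dASA-based interface definition.

ASA is computed with the Shrake-Rupley rolling-probe point-counting method
on a deterministic Fibonacci sphere lattice (no RNG; results are
bit-reproducible at fixed settings).  A residue is an interface residue if
its ASA drops by more than a small threshold upon complex formation
(default dASA > 0.1 A^2); the remaining residues are split into surface
and core by relative exposure of the free chain (default rASA >= 0.05).

Interface size counts interface residues of both chains pooled; interface
area is half the total buried dASA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .params import max_asa
from .structure_model import Atom, DimerComplex, Residue

DEFAULT_PROBE = 1.4       # Angstrom, water probe
DEFAULT_N_POINTS = 960    # lattice points per atom
DELTA_ASA_EPS = 1e-6      # numerical tolerance on dASA >= 0


def fibonacci_sphere(n_points: int) -> np.ndarray:
    """Deterministic, nearly uniform unit-sphere lattice (golden-spiral)."""
    i = np.arange(n_points, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - (2.0 * i + 1.0) / n_points
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def compute_sasa(atoms: list[Atom], probe: float = DEFAULT_PROBE,
                 n_points: int = DEFAULT_N_POINTS) -> np.ndarray:
    """Per-atom accessible surface area (A^2), Shrake-Rupley.

    Each atom is expanded by the probe radius; lattice points on the expanded
    sphere that fall inside any neighbouring expanded sphere are occluded.
    ASA = exposed fraction x sphere area.
    """
    if n_points < 60:
        raise ValueError("n_points must be >= 60 for a usable lattice")
    n = len(atoms)
    if n == 0:
        return np.zeros(0)
    coords = np.stack([a.coord for a in atoms])
    radii = np.array([a.vdw_radius for a in atoms], dtype=float)
    if not np.all(np.isfinite(radii)) or np.any(radii <= 0):
        raise ValueError("all atoms need positive vdW radii; "
                         "run assign_atom_classes first")
    expanded = radii + probe
    sphere = fibonacci_sphere(n_points)

    tree = cKDTree(coords)
    max_reach = 2.0 * expanded.max()
    pairs = tree.query_pairs(max_reach, output_type="ndarray")
    neighbors: list[list[int]] = [[] for _ in range(n)]
    for i, j in pairs:
        d = np.linalg.norm(coords[i] - coords[j])
        if d < 1e-9:
            warnings.warn(f"atoms {atoms[i].name} and {atoms[j].name} share "
                          f"identical coordinates")
        if d < expanded[i] + expanded[j]:
            neighbors[i].append(j)
            neighbors[j].append(i)

    asa = np.empty(n)
    for i in range(n):
        pts = coords[i] + expanded[i] * sphere
        exposed = np.ones(n_points, dtype=bool)
        for j in neighbors[i]:
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            exposed &= d2 > expanded[j] ** 2
        asa[i] = 4.0 * np.pi * expanded[i] ** 2 * exposed.sum() / n_points
    return asa


def residue_asa(atoms: list[Atom], per_atom: np.ndarray) -> dict[tuple, float]:
    """Sum per-atom ASA into per-residue totals keyed by residue key."""
    out: dict[tuple, float] = {}
    for atom, a in zip(atoms, per_atom):
        key = atom.residue_key()
        out[key] = out.get(key, 0.0) + float(a)
    return out


@dataclass
class ResidueASA:
    residue: Residue
    asa_bound: float     # A^2, in the complex
    asa_free: float      # A^2, chain alone
    rel_asa_free: float  # fraction of residue-type theoretical maximum

    @property
    def delta_asa(self) -> float:
        return self.asa_free - self.asa_bound


@dataclass
class InterfaceSet:
    """dASA partition of both chains into interface / surface / core."""

    interface: dict[str, list[Residue]] = field(default_factory=dict)
    surface: dict[str, list[Residue]] = field(default_factory=dict)
    core: dict[str, list[Residue]] = field(default_factory=dict)
    residue_asa: list[ResidueASA] = field(default_factory=list)
    interface_area: float = 0.0   # A^2, = sum(dASA)/2

    @property
    def interface_size(self) -> int:
        return sum(len(v) for v in self.interface.values())

    def interface_residues(self) -> list[Residue]:
        return [r for v in self.interface.values() for r in v]

    def surface_residues(self) -> list[Residue]:
        return [r for v in self.surface.values() for r in v]


def find_interface_residues(complex_: DimerComplex,
                            delta_threshold: float = 0.1,
                            exposure_cutoff: float = 0.05,
                            probe: float = DEFAULT_PROBE,
                            n_points: int = DEFAULT_N_POINTS) -> InterfaceSet:
    """Partition both chains into interface, surface and core residues.

    ASA is computed once for the complex and once for each isolated chain;
    a residue whose ASA drops by more than ``delta_threshold`` on
    complexation is interface.  Non-interface residues with free-chain
    relative exposure >= ``exposure_cutoff`` are surface; the rest are core.
    Chains not in contact give an empty interface (a valid result).
    """
    all_atoms = complex_.atoms()
    bound = residue_asa(all_atoms, compute_sasa(all_atoms, probe, n_points))

    result = InterfaceSet()
    total_delta = 0.0
    for chain_id, residues in complex_.chains().items():
        chain_atoms = [a for r in residues for a in r.atoms]
        free = residue_asa(chain_atoms, compute_sasa(chain_atoms, probe, n_points))
        iface, surf, core = [], [], []
        for res in residues:
            key = res.key()
            asa_free = free.get(key, 0.0)
            asa_bound = bound.get(key, 0.0)
            delta = asa_free - asa_bound
            if delta < -DELTA_ASA_EPS:
                warnings.warn(f"negative dASA {delta:.2e} for {res!r}; "
                              f"clamping to 0")
                delta = 0.0
            rel = asa_free / max_asa(res.name)
            result.residue_asa.append(ResidueASA(res, asa_bound, asa_free, rel))
            if delta > delta_threshold:
                iface.append(res)
                total_delta += delta
            elif rel >= exposure_cutoff:
                surf.append(res)
            else:
                core.append(res)
        result.interface[chain_id] = iface
        result.surface[chain_id] = surf
        result.core[chain_id] = core
    result.interface_area = total_delta / 2.0
    return result


def interface_table(iface: InterfaceSet) -> "pandas.DataFrame":  # noqa: F821
    """Per-residue TSV-ready table: chain, resseq, resname, ASAs, region."""
    import pandas as pd

    iface_keys = {r.key() for v in iface.interface.values() for r in v}
    surf_keys = {r.key() for v in iface.surface.values() for r in v}
    rows = []
    for ra in iface.residue_asa:
        key = ra.residue.key()
        region = ("interface" if key in iface_keys
                  else "surface" if key in surf_keys else "core")
        rows.append({
            "chain": ra.residue.chain_id, "resseq": ra.residue.seq,
            "resname": ra.residue.name,
            "asa_free": round(ra.asa_free, 3), "asa_bound": round(ra.asa_bound, 3),
            "delta_asa": round(ra.delta_asa, 3), "region": region,
        })
    return pd.DataFrame(rows)
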