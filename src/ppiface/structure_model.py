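"""Typed atomic model of a two-chain protein complex.

Parses PDB text into a :class:`DimerComplex` of exactly two protein chains,
dropping waters and all other HETATM ligands, resolving alternate locations
to the highest-occupancy conformer, and (separately) annotating every atom
with the interaction-relevant parameters: vdW radius, Lennard-Jones well
depth, formal charge and hydrogen-bond donor/acceptor class.

Hydrogen-bond chemistry is heavy-atom (donor/acceptor N,O) based because
X-ray structures mostly lack hydrogens.  Histidine is neutral by default and
chain termini carry no extra formal charge; both are configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np

from .params import AtomTypeTable, default_atom_table


@dataclass
class Atom:
    """One heavy (or hydrogen) atom with typing parameters attached."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_seq: int
    insertion_code: str
    chain_id: str
    coord: np.ndarray            # shape (3,), Angstrom
    occupancy: float = 1.0
    altloc: str = ""
    vdw_radius: float = float("nan")       # Angstrom (Rmin/2 convention)
    lj_well_depth: float = float("nan")    # kcal/mol
    charge: float = 0.0                    # formal/partial, elementary units
    hbond_class: str = "none"

    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_seq, self.insertion_code)


@dataclass
class Residue:
    name: str
    seq: int
    insertion_code: str
    chain_id: str
    atoms: list[Atom] = field(default_factory=list)

    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq, self.insertion_code)

    def __repr__(self) -> str:  # compact for test failure output
        return f"Residue({self.name} {self.chain_id}{self.seq}{self.insertion_code})"


@dataclass
class DimerComplex:
    """Two ordered protein chains; waters and ligands already removed."""

    pdb_id: str
    chain_a: list[Residue]
    chain_b: list[Residue]
    provenance: dict = field(default_factory=dict)

    @property
    def chain_a_id(self) -> str:
        return self.chain_a[0].chain_id

    @property
    def chain_b_id(self) -> str:
        return self.chain_b[0].chain_id

    def chains(self) -> dict[str, list[Residue]]:
        return {self.chain_a_id: self.chain_a, self.chain_b_id: self.chain_b}

    def atoms(self, chain: str | None = None) -> list[Atom]:
        if chain is None:
            residues = self.chain_a + self.chain_b
        else:
            residues = self.chains()[chain]
        return [a for r in residues for a in r.atoms]

    def coords(self, chain: str | None = None) -> np.ndarray:
        ats = self.atoms(chain)
        if not ats:
            return np.zeros((0, 3))
        return np.stack([a.coord for a in ats])

    def swapped(self) -> "DimerComplex":
        return DimerComplex(self.pdb_id, self.chain_b, self.chain_a,
                            dict(self.provenance))


class StructureError(ValueError):
    pass


def _validate_atom_lines(pdb_text: str) -> None:
    """Reject malformed ATOM/HETATM records with the offending line number.

    gemmi tolerates many malformations silently; this pre-scan enforces the
    fixed-column coordinate fields so errors are reported precisely.
    """
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        if not line.startswith(("ATOM  ", "HETATM")):
            continue
        if len(line) < 54:
            raise StructureError(f"malformed ATOM record at line {lineno}: too short")
        for lo, hi in ((30, 38), (38, 46), (46, 54)):
            try:
                float(line[lo:hi])
            except ValueError:
                raise StructureError(
                    f"malformed ATOM record at line {lineno}: bad coordinate "
                    f"field {line[lo:hi]!r}"
                ) from None


def _clean_altloc(altloc: str) -> str:
    return "" if altloc in ("", " ", "\0") else altloc


def _select_altloc(atoms: list[gemmi.Atom]) -> gemmi.Atom:
    """Highest occupancy wins; ties resolved by alphabetical altloc ('A' first)."""
    return max(atoms, key=lambda a: (a.occ, -ord(_clean_altloc(a.altloc) or "A")))


def parse_structure(pdb_text: str, chain_pair: tuple[str, str],
                    pdb_id: str = "XXXX", source: str = "<string>") -> DimerComplex:
    """Parse PDB text into a two-chain :class:`DimerComplex`.

    Waters (HOH) and all HETATM ligand records are removed.  For alternate
    locations the highest-occupancy conformer is kept (ties break to altloc
    'A').  Hydrogens are retained if present but nothing downstream requires
    them.

    Raises
    ------
    StructureError
        If a requested chain is missing or contains no protein residues, or
        an ATOM record is malformed (reported with its line number).
    """
    _validate_atom_lines(pdb_text)
    structure = gemmi.read_pdb_string(pdb_text)
    structure.setup_entities()
    if len(structure) == 0:
        raise StructureError("no models in structure")
    model = structure[0]
    available = [ch.name for ch in model]

    chains_out: list[list[Residue]] = []
    for want in chain_pair:
        chain = next((ch for ch in model if ch.name == want), None)
        if chain is None:
            raise StructureError(
                f"chain {want!r} not found; structure has chains {available}")
        residues: list[Residue] = []
        for res in chain:
            if res.name == "HOH" or res.het_flag == "H":
                continue  # waters neglected; ligand-mediated contacts out of scope
            out = Residue(name=res.name, seq=res.seqid.num,
                          insertion_code=(res.seqid.icode or "").strip(),
                          chain_id=want)
            by_name: dict[str, list[gemmi.Atom]] = {}
            for atom in res:
                by_name.setdefault(atom.name, []).append(atom)
            for name, group in by_name.items():
                g = _select_altloc(group)
                coord = np.array([g.pos.x, g.pos.y, g.pos.z], dtype=float)
                if not np.all(np.isfinite(coord)):
                    raise StructureError(
                        f"non-finite coordinates for atom {name} in "
                        f"{res.name} {want}{res.seqid.num}")
                out.atoms.append(Atom(
                    serial=g.serial, name=name, element=g.element.name.upper(),
                    residue_name=res.name, residue_seq=res.seqid.num,
                    insertion_code=(res.seqid.icode or "").strip(),
                    chain_id=want, coord=coord, occupancy=g.occ,
                    altloc=_clean_altloc(g.altloc),
                ))
            if out.atoms:
                residues.append(out)
        if not residues:
            raise StructureError(f"chain {want!r} has zero protein residues")
        chains_out.append(residues)

    return DimerComplex(
        pdb_id=pdb_id, chain_a=chains_out[0], chain_b=chains_out[1],
        provenance={"source": source, "chains": list(chain_pair)},
    )


def assign_atom_classes(complex_: DimerComplex,
                        table: AtomTypeTable | None = None,
                        charge_his: bool = False,
                        charge_termini: bool = False) -> DimerComplex:
    """Annotate every atom with radius, well depth, charge and H-bond class.

    Formal charges follow side-chain chemistry at physiological pH: Asp
    OD1/OD2 and Glu OE1/OE2 carry -0.5 each, Lys NZ +1, Arg NH1/NH2 +0.5
    each.  ``charge_his`` optionally protonates histidine (+0.5 on each ring
    nitrogen); ``charge_termini`` optionally charges the chain termini
    (N-terminal backbone N +1, C-terminal carboxylate oxygens -0.5 each).
    Unknown residue/atom combinations get element-default radius, zero
    charge, class ``none``, with a warning.

    Returns a new DimerComplex; the input is not modified.
    """
    table = table or default_atom_table()
    known_res = {res for res, _ in table.rules} | {"*"}

    def annotate(residues: list[Residue]) -> list[Residue]:
        out = []
        for i, res in enumerate(residues):
            new_atoms = []
            for atom in res.atoms:
                at = table.lookup(res.name, atom.name, atom.element)
                charge, hbclass = at.charge, at.hbond_class
                if res.name == "HIS" and charge_his and atom.name in ("ND1", "NE2"):
                    charge += 0.5
                if charge_termini:
                    if i == 0 and atom.name == "N":
                        charge += 1.0
                    if i == len(residues) - 1 and atom.name in ("O", "OXT"):
                        charge += -0.5
                # carbon/sulfur never donate or accept under the default model
                if atom.element in ("C", "S") and hbclass != "none":
                    hbclass = "none"
                new_atoms.append(replace(
                    atom, vdw_radius=at.radius, lj_well_depth=at.well_depth,
                    charge=charge, hbond_class=hbclass))
            out.append(Residue(res.name, res.seq, res.insertion_code,
                               res.chain_id, new_atoms))
        return out

    # warn once per unknown residue name (element defaults still apply)
    for res in complex_.chain_a + complex_.chain_b:
        if res.name not in known_res and res.name not in (
                "ALA", "GLY", "VAL", "LEU", "ILE", "PHE", "MET", "CYS"):
            warnings.warn(f"residue {res.name!r} not in typing table; "
                          f"element-default parameters assigned")

    return DimerComplex(
        pdb_id=complex_.pdb_id,
        chain_a=annotate(complex_.chain_a),
        chain_b=annotate(complex_.chain_b),
        provenance=dict(complex_.provenance),
    )


_PDB_LINE = ("{rec:<6s}{serial:5d} {name:<4s}{altloc:1s}{resname:>3s} "
             "{chain:1s}{resseq:4d}{icode:1s}   "
             "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{bfac:6.2f}          {el:>2s}")


def _format_atom_name(name: str, element: str) -> str:
    # element right-justified in columns 13-14 per wwPDB convention
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1:
        return f" {name:<3s}"
    return f"{name:<4s}"


def write_pdb(complex_: DimerComplex) -> str:
    """Serialize a DimerComplex back to PDB text (ATOM/TER records only)."""
    lines = []
    serial = 0
    for residues in (complex_.chain_a, complex_.chain_b):
        for res in residues:
            for atom in res.atoms:
                serial += 1
                lines.append(_PDB_LINE.format(
                    rec="ATOM", serial=serial,
                    name=_format_atom_name(atom.name, atom.element),
                    altloc=atom.altloc or " ", resname=res.name,
                    chain=res.chain_id, resseq=res.seq,
                    icode=atom.insertion_code or " ",
                    x=atom.coord[0], y=atom.coord[1], z=atom.coord[2],
                    occ=atom.occupancy, bfac=0.0, el=atom.element))
        serial += 1
        last = residues[-1]
        lines.append(f"TER   {serial:5d}      {last.name:>3s} "
                     f"{last.chain_id:1s}{last.seq:4d}")
    lines.append("END")
    return "\n".join(lines) + "\n"


def residue_formal_charge(residue: Residue) -> float:
    return sum(a.charge for a in residue.atoms)
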