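"""Atom-typing parameters: van der Waals radii, Lennard-Jones well depths,
formal charges and hydrogen-bond donor/acceptor classes.

The default table is AMBER-flavoured at the element level (radii are the
Rmin/2-style values, so the Lennard-Jones minimum of a pair sits at the sum
of the two radii) with residue-specific rows for formal charges and
donor/acceptor chemistry.  The table is a TSV with columns::

    residue_name  atom_name  radius  well_depth  charge  hbond_class

``residue_name`` may be ``*`` (any residue).  ``atom_name`` may be a plain
atom label or ``element:X`` to define an element-level default (``element:*``
is the last-resort fallback).  ``radius``/``well_depth`` entries of ``.``
inherit from the element default.  ``hbond_class`` is one of ``donor``,
``acceptor``, ``both``, ``none``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

HBOND_CLASSES = ("donor", "acceptor", "both", "none")


@dataclass
class AtomType:
    radius: float          # Angstrom, Rmin/2 convention
    well_depth: float      # kcal/mol
    charge: float          # elementary charge units
    hbond_class: str       # donor | acceptor | both | none


@dataclass
class AtomTypeTable:
    """Lookup table resolving (residue, atom, element) -> AtomType."""

    element_defaults: dict[str, tuple[float, float]] = field(default_factory=dict)
    rules: dict[tuple[str, str], tuple[float | None, float | None, float, str]] = field(
        default_factory=dict
    )

    def element_params(self, element: str) -> tuple[float, float]:
        el = element.upper()
        if el in self.element_defaults:
            return self.element_defaults[el]
        return self.element_defaults["*"]

    def lookup(self, residue_name: str, atom_name: str, element: str) -> AtomType:
        radius, well = self.element_params(element)
        charge, hbclass = 0.0, "none"
        # wildcard-residue rule first, specific residue rule overrides
        for key in (("*", atom_name), (residue_name, atom_name)):
            if key in self.rules:
                r, w, q, h = self.rules[key]
                radius = r if r is not None else radius
                well = w if w is not None else well
                charge, hbclass = q, h
        return AtomType(radius=radius, well_depth=well, charge=charge, hbond_class=hbclass)


def load_atom_table(path: str | Path | None = None) -> AtomTypeTable:
    """Load an atom-typing TSV; ``None`` loads the bundled default table."""
    if path is None:
        text = (resources.files("ppiface") / "data" / "atom_types.tsv").read_text()
    else:
        text = Path(path).read_text()
    table = AtomTypeTable()
    lines = text.strip().splitlines()
    header = lines[0].split("\t")
    expected = ["residue_name", "atom_name", "radius", "well_depth", "charge", "hbond_class"]
    if header != expected:
        raise ValueError(f"atom-typing table header must be {expected}, got {header}")
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        res, atom, radius_s, well_s, charge_s, hbclass = line.split("\t")
        if hbclass not in HBOND_CLASSES:
            raise ValueError(f"line {lineno}: unknown hbond_class {hbclass!r}")
        if atom.startswith("element:"):
            el = atom.split(":", 1)[1].upper()
            table.element_defaults[el] = (float(radius_s), float(well_s))
        else:
            radius = None if radius_s == "." else float(radius_s)
            well = None if well_s == "." else float(well_s)
            table.rules[(res, atom)] = (radius, well, float(charge_s), hbclass)
    if "*" not in table.element_defaults:
        raise ValueError("atom-typing table must define an 'element:*' fallback row")
    return table


_DEFAULT_TABLE: AtomTypeTable | None = None


def default_atom_table() -> AtomTypeTable:
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = load_atom_table(None)
    return _DEFAULT_TABLE


# Theoretical maximum accessible surface areas per residue type (Angstrom^2),
# used to normalise free-chain ASA into relative exposure (rASA).
MAX_ASA: dict[str, float] = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLU": 223.0, "GLN": 225.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}
_MAX_ASA_FALLBACK = 200.0


def max_asa(residue_name: str) -> float:
    try:
        return MAX_ASA[residue_name.upper()]
    except KeyError:
        warnings.warn(f"no theoretical max ASA for residue {residue_name!r}; using "
                      f"{_MAX_ASA_FALLBACK}")
        return _MAX_ASA_FALLBACK


# Non-polar residues used for interface polarity classification (configurable).
DEFAULT_NONPOLAR = frozenset(
    {"GLY", "ALA", "VAL", "LEU", "ILE", "PRO", "PHE", "MET", "TRP"}
)
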