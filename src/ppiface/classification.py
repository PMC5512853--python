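"""Functional-group annotation and residue-level interface polarity classes.

Complexes carry a manually curated molecular function (enzyme, regulator,
biological assembly, immune, enzyme inhibitor, regulator inhibitor) which
rolls up deterministically into obligatory / non-obligatory / immune.

Independently, each complex is classed by interface polarity: class A if the
interface has a strictly greater fraction of non-polar residues than the
(pooled, unbound-chain) surface, class B otherwise.  Ties go to class B
because class A is defined by a strict "more than".
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .params import DEFAULT_NONPOLAR
from .structure_model import Residue

FUNCTIONS = ("enzyme", "regulator", "biological_assembly", "immune",
             "enzyme_inhibitor", "regulator_inhibitor")

ROLLUP = {
    "enzyme": "obligatory",
    "regulator": "obligatory",
    "biological_assembly": "obligatory",
    "enzyme_inhibitor": "non-obligatory",
    "regulator_inhibitor": "non-obligatory",
    "immune": "immune",
}


@dataclass
class ComplexAnnotation:
    pdb_id: str
    chain_a: str
    chain_b: str
    function: str
    polarity_class: str | None = None   # "A" | "B" | None (unclassifiable)

    def __post_init__(self):
        if self.function not in FUNCTIONS:
            raise ValueError(f"unknown function {self.function!r}; "
                             f"expected one of {FUNCTIONS}")

    @property
    def rollup(self) -> str:
        return ROLLUP[self.function]


def nonpolar_fraction(residues: list[Residue],
                      nonpolar_set: frozenset = DEFAULT_NONPOLAR) -> float:
    """Fraction of residues whose 3-letter code is in the non-polar set."""
    if not residues:
        raise ValueError("empty residue list; caller must skip")
    hits = sum(1 for r in residues if r.name.upper() in nonpolar_set)
    return hits / len(residues)


def classify_polarity(interface_residues: list[Residue],
                      surface_residues: list[Residue],
                      nonpolar_set: frozenset = DEFAULT_NONPOLAR) -> str | None:
    """Class A iff the interface is strictly more non-polar than the surface.

    Returns ``None`` (unclassifiable) if either list is empty — e.g. a
    non-contacting pair with no interface.
    """
    if not interface_residues or not surface_residues:
        return None
    f_iface = nonpolar_fraction(interface_residues, nonpolar_set)
    f_surf = nonpolar_fraction(surface_residues, nonpolar_set)
    return "A" if f_iface > f_surf else "B"


def read_annotations(path: str | Path) -> list[ComplexAnnotation]:
    """Read the annotation TSV: pdb_id, chain_a, chain_b, function."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"pdb_id", "chain_a", "chain_b", "function"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    return [ComplexAnnotation(row.pdb_id, row.chain_a, row.chain_b, row.function)
            for row in df.itertuples()]


def annotations_table(annotations: list[ComplexAnnotation]) -> pd.DataFrame:
    """Annotation table with derived rollup and polarity columns appended."""
    return pd.DataFrame([{
        "pdb_id": a.pdb_id, "chain_a": a.chain_a, "chain_b": a.chain_b,
        "function": a.function, "rollup": a.rollup,
        "polarity_class": a.polarity_class or "unclassified",
    } for a in annotations])
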