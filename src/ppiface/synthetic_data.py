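"""Synthetic inputs with known ground truth.

Two generators:

* :func:`build_toy_dimer` — idealised two-chain structures in PDB format
  with *planted, countable* inter-chain interactions.  Hydrogen-bond pairs
  are placed at 2.8-3.2 A, salt bridges at charged-group separations of
  3.6-4.9 A (inside the electrostatic cutoff, outside the H-bond cutoff so
  the channel counts stay independent), remaining interface residues pack at
  vdW-contact distance, and non-interface residues sit > 12 A from the
  partner chain.  Residue identities are chosen to force the requested
  interface polarity class.  Geometry is deliberately idealised (residues on
  a regular pitch, compact side-chain templates, no Ramachandran realism):
  every downstream computation is distance- or area-based, so this is
  sufficient to make detection counts exactly predictable.

* :func:`build_energy_table` — per-complex energy tables emulating the
  statistical structure of a hetero-dimer survey: interface sizes uniform on
  a stated range, each channel energy linear in size plus Gaussian noise
  (with the noise derivable from a requested population R^2 via
  ``R^2 = slope^2 Var(size) / (slope^2 Var(size) + sigma^2)``), or channel
  percentages drawn around stated mean/SD targets.

Every generator takes an explicit seed and uses a single private RNG
stream; the same spec is byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .decomposition import decompose_totals
from .structure_model import Atom, DimerComplex, Residue, write_pdb

PITCH = 13.0          # A between interface slots; > vdW cutoff + excursions
FAR_OFFSET = 18.0     # A from the contact plane for non-interface residues

# residue templates: (atom_name, element, local offset) with the front atom
# at the origin and the chain body extending along -y (toward own chain side)
_TEMPLATES: dict[str, list[tuple[str, str, tuple[float, float, float]]]] = {
    "GLY_N": [  # front atom: backbone N (H-bond donor)
        ("N", "N", (0.0, 0.0, 0.0)),
        ("CA", "C", (0.4, -1.4, 0.2)),
        ("C", "C", (-0.4, -2.6, -0.2)),
        ("O", "O", (0.5, -3.4, 0.3)),
    ],
    "GLY_O": [  # front atom: backbone O (H-bond acceptor)
        ("O", "O", (0.0, 0.0, 0.0)),
        ("C", "C", (0.3, -1.3, 0.2)),
        ("CA", "C", (-0.4, -2.5, -0.2)),
        ("N", "N", (0.4, -3.7, 0.3)),
    ],
    "LYS": [  # front atom: NZ (+1)
        ("NZ", "N", (0.0, 0.0, 0.0)),
        ("CB", "C", (0.3, -1.6, 0.2)),
        ("CA", "C", (-0.3, -2.9, -0.2)),
        ("N", "N", (0.6, -3.9, 0.3)),
        ("C", "C", (-0.6, -4.1, 0.4)),
        ("O", "O", (0.1, -5.2, -0.3)),
    ],
    "ASP": [  # front atoms: OD1/OD2 (-0.5 each)
        ("OD1", "O", (0.0, 0.0, 0.8)),
        ("OD2", "O", (0.0, 0.0, -0.8)),
        ("CG", "C", (0.2, -1.2, 0.0)),
        ("CB", "C", (-0.3, -2.5, 0.2)),
        ("CA", "C", (0.3, -3.8, -0.2)),
        ("N", "N", (-0.5, -4.8, 0.3)),
        ("C", "C", (0.9, -4.6, 0.2)),
        ("O", "O", (1.2, -5.7, -0.2)),
    ],
    "LEU": [  # front atom: CB (non-polar packing)
        ("CB", "C", (0.0, 0.0, 0.0)),
        ("CG", "C", (0.2, -1.5, 0.3)),
        ("CA", "C", (-0.4, -2.7, -0.2)),
        ("N", "N", (0.5, -3.8, 0.3)),
        ("C", "C", (-0.6, -4.0, 0.2)),
        ("O", "O", (0.0, -5.1, -0.3)),
    ],
    "SER": [  # front atom: CB (polar residue, OG kept behind)
        ("CB", "C", (0.0, 0.0, 0.0)),
        ("OG", "O", (0.8, -1.2, 0.4)),
        ("CA", "C", (-0.5, -2.6, -0.2)),
        ("N", "N", (0.4, -3.7, 0.3)),
        ("C", "C", (-0.7, -3.9, 0.2)),
        ("O", "O", (-0.1, -5.0, -0.3)),
    ],
}
_RESNAME = {"GLY_N": "GLY", "GLY_O": "GLY", "LYS": "LYS", "ASP": "ASP",
            "LEU": "LEU", "SER": "SER"}


@dataclass
class DimerSpec:
    """Recipe for one toy dimer with planted interactions."""

    n_residues: int = 12              # per chain
    n_planted_hbonds: int = 2
    n_planted_saltbridges: int = 1
    interface_contact_fraction: float = 0.5
    polarity_target: str = "A"        # "A" | "B"
    seed: int = 0

    @property
    def n_interface(self) -> int:
        """Interface residues per chain implied by the contact fraction."""
        return int(round(self.interface_contact_fraction * self.n_residues))

    @property
    def expected_hbonds(self) -> int:
        return self.n_planted_hbonds

    @property
    def expected_charged_pairs(self) -> int:
        # one Lys NZ against both carboxylate oxygens per salt bridge
        return 2 * self.n_planted_saltbridges

    def validate(self) -> None:
        if self.polarity_target not in ("A", "B"):
            raise ValueError("polarity_target must be 'A' or 'B'")
        if not 0.0 <= self.interface_contact_fraction <= 1.0:
            raise ValueError("interface_contact_fraction must be in [0, 1]")
        planted = self.n_planted_hbonds + self.n_planted_saltbridges
        if planted > self.n_interface:
            raise ValueError(
                f"cannot plant {planted} interaction pairs in "
                f"{self.n_interface} interface residues per chain")
        if (self.polarity_target == "A" and self.n_interface > 0
                and self.n_interface == self.n_planted_saltbridges):
            raise ValueError("polarity target A needs at least one non-polar "
                             "interface residue (all slots are salt bridges)")


def _place(template_key: str, front: np.ndarray, facing: float,
           chain_id: str, seq: int) -> Residue:
    """Instantiate a template at ``front``; ``facing=+1`` means the partner
    chain lies toward +y, so the residue body extends to -y (and mirrored
    for ``facing=-1``)."""
    name = _RESNAME[template_key]
    res = Residue(name=name, seq=seq, insertion_code="", chain_id=chain_id)
    for atom_name, element, (dx, dy, dz) in _TEMPLATES[template_key]:
        coord = front + np.array([dx, facing * dy, dz])
        res.atoms.append(Atom(
            serial=0, name=atom_name, element=element, residue_name=name,
            residue_seq=seq, insertion_code="", chain_id=chain_id,
            coord=np.round(coord, 3)))
    return res


def build_toy_dimer(spec: DimerSpec) -> str:
    """Generate PDB text for a two-chain toy dimer described by ``spec``.

    Interface slot layout along x (pitch 13 A): first the planted H-bond
    pairs, then the salt bridges, then vdW-packed filler residues whose
    identity (Leu vs Ser) forces the polarity target.  Non-interface
    residues continue the x grid but are displaced 18 A away from the
    contact plane on each side.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_iface = spec.n_interface
    n_filler = n_iface - spec.n_planted_hbonds - spec.n_planted_saltbridges
    iface_filler = "LEU" if spec.polarity_target == "A" else "SER"
    far_filler = "SER" if spec.polarity_target == "A" else "LEU"

    chain_a: list[Residue] = []
    chain_b: list[Residue] = []
    slot = 0
    for _ in range(spec.n_planted_hbonds):
        x = slot * PITCH
        d = float(rng.uniform(2.8, 3.2))
        z = float(rng.uniform(-0.3, 0.3))
        chain_a.append(_place("GLY_N", np.array([x, 0.0, z]), +1.0, "A", slot + 1))
        chain_b.append(_place("GLY_O", np.array([x, d, z]), -1.0, "B", slot + 1))
        slot += 1
    for _ in range(spec.n_planted_saltbridges):
        x = slot * PITCH
        d = float(rng.uniform(3.6, 4.9))   # NZ..OD in (3.5, 6.0): elec only
        z = float(rng.uniform(-0.3, 0.3))
        chain_a.append(_place("LYS", np.array([x, 0.0, z]), +1.0, "A", slot + 1))
        chain_b.append(_place("ASP", np.array([x, d, z]), -1.0, "B", slot + 1))
        slot += 1
    for _ in range(n_filler):
        x = slot * PITCH
        d = float(rng.uniform(3.7, 4.0))   # CB..CB near the LJ minimum
        z = float(rng.uniform(-0.3, 0.3))
        chain_a.append(_place(iface_filler, np.array([x, 0.0, z]), +1.0, "A", slot + 1))
        chain_b.append(_place(iface_filler, np.array([x, d, z]), -1.0, "B", slot + 1))
        slot += 1
    for _ in range(spec.n_residues - n_iface):
        x = slot * PITCH
        chain_a.append(_place(far_filler, np.array([x, -FAR_OFFSET, 0.0]),
                              +1.0, "A", slot + 1))
        chain_b.append(_place(far_filler, np.array([x, FAR_OFFSET + 4.0, 0.0]),
                              -1.0, "B", slot + 1))
        slot += 1

    complex_ = DimerComplex(pdb_id=f"SY{spec.seed % 100:02d}",
                            chain_a=chain_a, chain_b=chain_b,
                            provenance={"generator": "build_toy_dimer",
                                        "spec": vars(spec).copy()})
    return write_pdb(complex_)


# ---------------------------------------------------------------------------
# SD-style per-complex energy tables
# ---------------------------------------------------------------------------

#: functional-group composition of a 278-complex hetero-dimer survey
DEFAULT_GROUP_SIZES: dict[str, int] = {
    "enzyme": 40, "regulator": 144, "biological_assembly": 24,
    "immune": 18, "enzyme_inhibitor": 25, "regulator_inhibitor": 27,
}

DEFAULT_SIZE_RANGE = (20, 120)   # interface residues, both chains pooled


@dataclass
class LinearRelation:
    """One channel's size-energy law: |E| = slope*size + intercept + noise."""

    slope: float
    intercept: float = 0.0
    sigma: float | None = None          # kcal/mol; derived if None
    population_r2: float | None = None  # used to derive sigma if given

    def resolve_sigma(self, size_var: float) -> float:
        if self.sigma is not None:
            return self.sigma
        if self.population_r2 is None:
            return 0.0
        r2 = self.population_r2
        if not 0.0 < r2 <= 1.0:
            raise ValueError("population_r2 must be in (0, 1]")
        return abs(self.slope) * np.sqrt(size_var) * np.sqrt((1.0 - r2) / r2)


def discrete_uniform_variance(lo: int, hi: int) -> float:
    """Variance of the integer-uniform size distribution on [lo, hi]."""
    span = hi - lo + 1
    return (span * span - 1) / 12.0


@dataclass
class TableSpec:
    """Recipe for a per-complex energy table with known ground truth."""

    n_complexes: int = 278
    group_sizes: dict[str, int] | None = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    size_range: tuple[int, int] = DEFAULT_SIZE_RANGE
    # linear mode: per-channel size-energy laws (defaults mirror a survey
    # where vdW dominates ~75% and tracks size tightly)
    relations: dict[str, LinearRelation] = field(default_factory=lambda: {
        "vdw": LinearRelation(slope=2.0, intercept=30.0, population_r2=0.87),
        "hbond": LinearRelation(slope=0.4, intercept=8.0, population_r2=0.53),
        "elec": LinearRelation(slope=0.25, intercept=5.0, population_r2=0.15),
    })
    # percentage mode (overrides linear mode when set): channel -> (mean, sd)
    pct_targets: dict[str, tuple[float, float]] | None = None
    polarity_class: str | None = None   # label applied to every row, if any
    seed: int = 0

    def validate(self) -> None:
        if self.n_complexes < 1:
            raise ValueError("n_complexes must be >= 1")
        if self.group_sizes is not None:
            total = sum(self.group_sizes.values())
            if total != self.n_complexes:
                raise ValueError(f"group sizes sum to {total}, "
                                 f"expected {self.n_complexes}")
        for rel in self.relations.values():
            if rel.sigma is not None and rel.sigma < 0:
                raise ValueError("sigma must be >= 0")


def build_energy_table(spec: TableSpec) -> pd.DataFrame:
    """Generate an SD-style per-complex table (one row per complex).

    Columns: pdb_id, function, rollup, polarity_class, interface_size,
    e_vdw, e_hbond, e_elec, e_total, pct_vdw, pct_hbond, pct_elec,
    elec_unfavorable_flag.  Energies are stored signed (favourable
    negative); percentages follow the decomposition caveat rule.
    """
    from .classification import ROLLUP

    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_complexes
    lo, hi = spec.size_range
    sizes = rng.integers(lo, hi + 1, size=n)

    if spec.pct_targets is not None:
        total_mag = 2.7 * sizes + 30.0
        mv, sv = spec.pct_targets.get("vdw", (74.93, 11.37))
        mh, sh = spec.pct_targets.get("hbond", (15.03, 6.54))
        pct_vdw = np.clip(rng.normal(mv, sv, size=n), 0.0, 100.0)
        pct_hbond = np.clip(rng.normal(mh, sh, size=n), 0.0, 100.0 - pct_vdw)
        pct_elec = 100.0 - pct_vdw - pct_hbond
        mags = {"vdw": pct_vdw / 100.0 * total_mag,
                "hbond": pct_hbond / 100.0 * total_mag,
                "elec": pct_elec / 100.0 * total_mag}
    else:
        size_var = discrete_uniform_variance(lo, hi)
        mags = {}
        for comp in ("vdw", "hbond", "elec"):
            rel = spec.relations[comp]
            sigma = rel.resolve_sigma(size_var)
            mags[comp] = (rel.slope * sizes + rel.intercept
                          + rng.normal(0.0, sigma, size=n) if sigma > 0
                          else rel.slope * sizes + rel.intercept
                          + np.zeros(n))

    if spec.group_sizes is not None:
        functions = np.repeat(list(spec.group_sizes.keys()),
                              list(spec.group_sizes.values()))
    else:
        functions = np.array(["unannotated"] * n)

    rows = []
    for i in range(n):
        d = decompose_totals(-float(mags["vdw"][i]), -float(mags["hbond"][i]),
                             -float(mags["elec"][i]))
        func = str(functions[i])
        rows.append({
            "pdb_id": f"S{i:04d}", "function": func,
            "rollup": ROLLUP.get(func, "unannotated"),
            "polarity_class": spec.polarity_class,
            "interface_size": int(sizes[i]),
            "e_vdw": d.e_vdw, "e_hbond": d.e_hbond, "e_elec": d.e_elec,
            "e_total": d.e_total,
            "pct_vdw": d.pct_vdw, "pct_hbond": d.pct_hbond,
            "pct_elec": d.pct_elec,
            "elec_unfavorable_flag": d.elec_unfavorable,
        })
    return pd.DataFrame(rows)


def build_synthetic_dataset(n_complexes: int, out_dir, seed: int = 0,
                            n_residues: int = 10) -> "pathlib.Path":  # noqa: F821
    """Write a batch of toy dimers plus an annotation TSV; returns the
    annotation path.  Used by the batch pipeline and its tests."""
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    from .classification import FUNCTIONS

    rows = []
    for i in range(n_complexes):
        sub = int(rng.integers(0, 2 ** 31 - 1))
        spec = DimerSpec(
            n_residues=n_residues,
            n_planted_hbonds=int(rng.integers(1, 4)),
            n_planted_saltbridges=int(rng.integers(0, 2)),
            interface_contact_fraction=float(rng.uniform(0.4, 0.8)),
            polarity_target=str(rng.choice(["A", "B"])),
            seed=sub,
        )
        pdb_id = f"T{i:03d}"
        (out_dir / f"{pdb_id}.pdb").write_text(build_toy_dimer(spec))
        rows.append({"pdb_id": pdb_id, "chain_a": "A", "chain_b": "B",
                     "function": FUNCTIONS[i % len(FUNCTIONS)]})
    ann = out_dir / "annotations.tsv"
    pd.DataFrame(rows).to_csv(ann, sep="\t", index=False)
    return ann
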