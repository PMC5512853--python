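"""Per-complex analysis and dataset-level reporting.

:func:`run_complex` takes one two-chain structure through the full chain:
parse -> atom typing -> dASA interface -> interaction detection ->
energy decomposition -> polarity class.  :func:`run_dataset` batches it over
an annotation table with per-complex error isolation and emits the
per-complex results CSV plus the group-level regression and summary
reports.  Every output directory receives the serialized RunConfig for
provenance; identical config and inputs reproduce identical CSVs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import interactions as ia
from . import sasa_interface as si
from .classification import ComplexAnnotation, classify_polarity, read_annotations
from .decomposition import EnergyDecomposition, decompose, decomposition_row
from .group_stats import regression_table, summarize, summary_table
from .params import DEFAULT_NONPOLAR, load_atom_table
from .structure_model import DimerComplex, assign_atom_classes, parse_structure

log = logging.getLogger("ppiface")


@dataclass
class RunConfig:
    """All tunables of one analysis run; serialized alongside every output."""

    hbond_cutoff: float = ia.DEFAULT_HBOND_CUTOFF
    elec_cutoff: float = ia.DEFAULT_ELEC_CUTOFF
    vdw_cutoff: float = ia.DEFAULT_VDW_CUTOFF
    hbond_d_opt: float = ia.HBOND_OPTIMAL
    hbond_e0: float = ia.HBOND_E0
    probe: float = si.DEFAULT_PROBE
    n_points: int = si.DEFAULT_N_POINTS
    delta_asa_threshold: float = 0.1
    exposure_cutoff: float = 0.05
    nonpolar_set: list[str] = field(default_factory=lambda: sorted(DEFAULT_NONPOLAR))
    atom_table: str | None = None      # path to a typing TSV; None = bundled
    charge_his: bool = False
    charge_termini: bool = False
    grouping: str = "function"         # function | rollup | polarity_class

    def __post_init__(self):
        for name in ("hbond_cutoff", "elec_cutoff", "vdw_cutoff", "probe"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text))


@dataclass
class ComplexResult:
    pdb_id: str
    chains: tuple[str, str]
    complex: DimerComplex
    interface: si.InterfaceSet
    records: list[ia.InteractionRecord]
    decomposition: EnergyDecomposition
    polarity_class: str | None

    def row(self) -> dict:
        r = decomposition_row(self.pdb_id, "".join(self.chains),
                              self.interface.interface_size,
                              self.interface.interface_area,
                              self.decomposition)
        r["polarity_class"] = self.polarity_class
        counts = {"n_hbond": 0, "n_elec": 0, "n_vdw": 0}
        keymap = {"hbond": "n_hbond", "electrostatic": "n_elec", "vdw": "n_vdw"}
        for rec in self.records:
            counts[keymap[rec.kind]] += 1
        r.update(counts)
        return r


def analyze_complex(complex_: DimerComplex, config: RunConfig) -> ComplexResult:
    """Full analysis of an already-parsed complex."""
    table = load_atom_table(config.atom_table) if config.atom_table else None
    typed = assign_atom_classes(complex_, table, charge_his=config.charge_his,
                                charge_termini=config.charge_termini)
    iface = si.find_interface_residues(
        typed, delta_threshold=config.delta_asa_threshold,
        exposure_cutoff=config.exposure_cutoff,
        probe=config.probe, n_points=config.n_points)
    records = (ia.detect_hbonds(typed, config.hbond_cutoff,
                                config.hbond_d_opt, config.hbond_e0)
               + ia.detect_electrostatics(typed, config.elec_cutoff)
               + ia.compute_vdw(typed, config.vdw_cutoff))
    decomp = decompose(records)
    polarity = classify_polarity(iface.interface_residues(),
                                 iface.surface_residues(),
                                 frozenset(config.nonpolar_set))
    n_by_kind = {k: sum(r.kind == k for r in records)
                 for k in ("hbond", "electrostatic", "vdw")}
    log.info("%s: interface_size=%d contacts=%s", typed.pdb_id,
             iface.interface_size, n_by_kind)
    return ComplexResult(
        pdb_id=typed.pdb_id, chains=(typed.chain_a_id, typed.chain_b_id),
        complex=typed, interface=iface, records=records,
        decomposition=decomp, polarity_class=polarity)


def run_complex(structure_path: str | Path, chain_pair: tuple[str, str],
                config: RunConfig | None = None,
                out_dir: str | Path | None = None) -> ComplexResult:
    """Analyze one structure file; optionally write per-complex outputs.

    Outputs (when ``out_dir`` is given): ``<id>_interface.tsv`` (per-residue
    ASA partition), ``<id>_interactions.tsv`` (per-contact energies),
    ``<id>_summary.json`` and ``config.json``.
    """
    config = config or RunConfig()
    structure_path = Path(structure_path)
    pdb_id = structure_path.stem[:4].upper()
    complex_ = parse_structure(structure_path.read_text(), chain_pair,
                               pdb_id=pdb_id, source=str(structure_path))
    result = analyze_complex(complex_, config)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        si.interface_table(result.interface).to_csv(
            out_dir / f"{pdb_id}_interface.tsv", sep="\t", index=False)
        ia.interactions_table(result.records).to_csv(
            out_dir / f"{pdb_id}_interactions.tsv", sep="\t", index=False)
        (out_dir / f"{pdb_id}_summary.json").write_text(
            json.dumps(result.row(), indent=2, default=str) + "\n")
        (out_dir / "config.json").write_text(config.to_json() + "\n")
    return result


def run_dataset(annotation_path: str | Path, pdb_dir: str | Path,
                config: RunConfig | None = None,
                out_dir: str | Path | None = None
                ) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Batch analysis over an annotation table.

    Per-complex failures are logged and skipped; the run continues.  Returns
    the per-complex results table and the report tables (regressions and
    percentage summaries per grouping scheme), writing them under
    ``out_dir`` when given.
    """
    config = config or RunConfig()
    annotations = read_annotations(annotation_path)
    if not annotations:
        raise ValueError("annotation table is empty")
    pdb_dir = Path(pdb_dir)

    rows, failures = [], []
    for ann in annotations:
        path = pdb_dir / f"{ann.pdb_id}.pdb"
        try:
            result = run_complex(path, (ann.chain_a, ann.chain_b), config)
        except Exception as exc:  # per-complex isolation
            log.warning("%s failed: %s", ann.pdb_id, exc)
            failures.append({"pdb_id": ann.pdb_id, "error": str(exc)})
            continue
        ann.polarity_class = result.polarity_class
        row = result.row()
        row["function"] = ann.function
        row["rollup"] = ann.rollup
        rows.append(row)
    results = pd.DataFrame(rows)
    reports = build_reports(results) if len(results) else {}

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        results.to_csv(out_dir / "per_complex.csv", index=False)
        for name, table in reports.items():
            table.to_csv(out_dir / f"{name}.csv", index=False)
        if failures:
            pd.DataFrame(failures).to_csv(out_dir / "failures.csv", index=False)
        (out_dir / "config.json").write_text(config.to_json() + "\n")
    return results, reports


def build_reports(results: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Group-level reports: size-energy r^2 tables per functional group and
    polarity class, and mean/SD percentage tables for the same groupings."""
    reports: dict[str, pd.DataFrame] = {}
    frame = results.copy()
    frame["all"] = "all"
    groupings = [("all", "all"), ("function", "function"),
                 ("rollup", "rollup"), ("polarity_class", "polarity_class")]
    for label, col in groupings:
        if col not in frame.columns or frame[col].isna().all():
            continue
        reg = regression_table(frame, col)
        if len(reg):
            reports[f"regression_by_{label}"] = reg
        summ = summary_table(summarize(frame, col))
        if len(summ):
            reports[f"summary_by_{label}"] = summ
    return reports
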