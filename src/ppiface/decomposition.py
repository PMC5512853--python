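"""Per-complex energy totals and percentage decomposition.

The total interface pseudo-energy is the sum of the vdW, H-bond and
electrostatic channel totals.  Percentages are computed on the magnitudes of
the *favourable* components: a channel whose net total is repulsive
(positive) — in practice electrostatics, when like-charge repulsion across
the interface outweighs attraction — is flagged and contributes 0% while its
signed value is preserved in the output.  The rule is applied per complex on
the net channel total, not per contact.
"""

from __future__ import annotations

from dataclasses import dataclass

from .interactions import InteractionRecord


@dataclass
class EnergyDecomposition:
    e_vdw: float
    e_hbond: float
    e_elec: float
    elec_unfavorable: bool = False
    pct_vdw: float | None = None
    pct_hbond: float | None = None
    pct_elec: float | None = None

    @property
    def e_total(self) -> float:
        return self.e_vdw + self.e_hbond + self.e_elec

    @property
    def e_total_favorable(self) -> float:
        """Total with any net-repulsive channel dropped (the caveat rule)."""
        return sum(e for e in (self.e_vdw, self.e_hbond, self.e_elec) if e < 0)

    @property
    def defined(self) -> bool:
        """False when no favourable energy exists (empty interface sentinel)."""
        return self.pct_vdw is not None


def decompose(records: list[InteractionRecord]) -> EnergyDecomposition:
    """Aggregate one complex's interaction records into an EnergyDecomposition.

    An empty record list (or one with no net-favourable channel) yields all
    totals 0 and undefined percentages (``defined`` is False); callers must
    not propagate NaN arithmetic from such complexes.
    """
    totals = {"vdw": 0.0, "hbond": 0.0, "electrostatic": 0.0}
    for r in records:
        totals[r.kind] += r.energy
    return decompose_totals(totals["vdw"], totals["hbond"], totals["electrostatic"])


def decompose_totals(e_vdw: float, e_hbond: float,
                     e_elec: float) -> EnergyDecomposition:
    """Percentage decomposition from channel totals (kcal/mol, signed).

    Favourable magnitude of each channel is ``max(0, -e)``; percentages are
    each favourable magnitude over their sum, times 100, so they sum to 100
    whenever any favourable energy exists.
    """
    out = EnergyDecomposition(e_vdw=e_vdw, e_hbond=e_hbond, e_elec=e_elec,
                              elec_unfavorable=e_elec > 0)
    fav = {k: max(0.0, -e) for k, e in
           (("vdw", e_vdw), ("hbond", e_hbond), ("elec", e_elec))}
    denom = sum(fav.values())
    if denom > 0:
        out.pct_vdw = 100.0 * fav["vdw"] / denom
        out.pct_hbond = 100.0 * fav["hbond"] / denom
        out.pct_elec = 100.0 * fav["elec"] / denom
    return out


def decomposition_row(pdb_id: str, chains: str, interface_size: int,
                      interface_area: float,
                      d: EnergyDecomposition) -> dict:
    """One row of the per-complex results CSV."""
    return {
        "pdb_id": pdb_id, "chains": chains,
        "interface_size": interface_size,
        "interface_area": round(interface_area, 2),
        "e_vdw": round(d.e_vdw, 4), "e_hbond": round(d.e_hbond, 4),
        "e_elec": round(d.e_elec, 4), "e_total": round(d.e_total, 4),
        "pct_vdw": None if d.pct_vdw is None else round(d.pct_vdw, 2),
        "pct_hbond": None if d.pct_hbond is None else round(d.pct_hbond, 2),
        "pct_elec": None if d.pct_elec is None else round(d.pct_elec, 2),
        "elec_unfavorable_flag": d.elec_unfavorable,
    }
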