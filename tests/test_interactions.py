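"""Distance-cutoff detection and pseudo-energy scoring of contacts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ppiface.interactions import (COULOMB_CONSTANT, compute_vdw, detect_all,
                                  detect_electrostatics, detect_hbonds,
                                  hbond_energy, lj_energy)
from ppiface.structure_model import DimerComplex, Residue
from ppiface.synthetic_data import DimerSpec

from conftest import make_atom, toy_complex


def pair_complex(atom_a, atom_b):
    """Two one-residue chains holding the given atoms."""
    ra = Residue("ALA", 1, "", "A", [atom_a])
    rb = Residue("ALA", 1, "", "B", [atom_b])
    return DimerComplex("PAIR", [ra], [rb])


class TestHbonds:
    def test_planted_backbone_pair(self):
        cx = pair_complex(
            make_atom("N", "N", (0, 0, 0), radius=1.824, hbclass="donor"),
            make_atom("O", "O", (2.9, 0, 0), radius=1.661, hbclass="acceptor",
                      chain="B"))
        records = detect_hbonds(cx)
        assert len(records) == 1
        assert records[0].energy < 0
        assert records[0].distance == pytest.approx(2.9)

    def test_beyond_cutoff_excluded(self):
        cx = pair_complex(
            make_atom("N", "N", (0, 0, 0), hbclass="donor"),
            make_atom("O", "O", (3.8, 0, 0), hbclass="acceptor", chain="B"))
        assert detect_hbonds(cx) == []

    def test_requires_donor_acceptor_pairing(self):
        # two donors cannot bond
        cx = pair_complex(
            make_atom("N", "N", (0, 0, 0), hbclass="donor"),
            make_atom("N", "N", (2.9, 0, 0), hbclass="donor", chain="B"))
        assert detect_hbonds(cx) == []

    def test_planted_pairs_match_brute_force(self):
        cx = toy_complex(DimerSpec(n_residues=12, n_planted_hbonds=5,
                                   n_planted_saltbridges=0,
                                   interface_contact_fraction=0.5,
                                   polarity_target="A", seed=11))
        grid = detect_hbonds(cx, method="grid")
        brute = detect_hbonds(cx, method="brute")
        assert len(grid) == 5
        assert [r.key() for r in grid] == [r.key() for r in brute]

    def test_energy_well_shape(self):
        assert hbond_energy(2.8) == pytest.approx(-2.0)       # optimum
        assert hbond_energy(3.5) == pytest.approx(0.0)        # cutoff
        assert hbond_energy(2.5) == pytest.approx(-2.0)       # clamped
        assert -2.0 < hbond_energy(3.1) < 0.0

    @given(st.floats(min_value=2.0, max_value=3.5))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_energy_bounded(self, d):
        assert -2.0 <= hbond_energy(d) <= 0.0


class TestElectrostatics:
    def test_salt_bridge_formula_oracle(self):
        # Lys NZ (+1) against each Asp carboxylate oxygen (-0.5) at 4 A:
        # E = 332.0637 * (+1)(-0.5) / (16 * 4) per pair
        nz = make_atom("NZ", "N", (0, 0, 0), charge=1.0, resname="LYS")
        od1 = make_atom("OD1", "O", (4, 0, 0), charge=-0.5, resname="ASP",
                        chain="B")
        od2 = make_atom("OD2", "O", (0, 4, 0), charge=-0.5, resname="ASP",
                        chain="B")
        ra = Residue("LYS", 1, "", "A", [nz])
        rb = Residue("ASP", 1, "", "B", [od1, od2])
        records = detect_electrostatics(DimerComplex("SALT", [ra], [rb]))
        expected = COULOMB_CONSTANT * 1.0 * -0.5 / (4.0 * 4.0 * 4.0)
        assert len(records) == 2
        for r in records:
            assert r.energy == pytest.approx(expected)   # ~ -2.594 kcal/mol
            assert r.energy == pytest.approx(-2.594, abs=2e-3)

    def test_like_charges_repulsive(self):
        cx = pair_complex(
            make_atom("NZ", "N", (0, 0, 0), charge=1.0, resname="LYS"),
            make_atom("NH1", "N", (5, 0, 0), charge=0.5, resname="ARG",
                      chain="B"))
        records = detect_electrostatics(cx)
        assert len(records) == 1
        assert records[0].energy > 0

    def test_neutral_complex_empty(self):
        cx = toy_complex(DimerSpec(n_residues=8, n_planted_hbonds=2,
                                   n_planted_saltbridges=0,
                                   interface_contact_fraction=0.5,
                                   polarity_target="A", seed=2))
        assert detect_electrostatics(cx) == []


class TestVdw:
    def test_minimum_at_rmin(self):
        # d = r_i + r_j exactly -> E = -eps_ij
        cx = pair_complex(make_atom(xyz=(0, 0, 0)),
                          make_atom(xyz=(2 * 1.908, 0, 0), chain="B"))
        records = compute_vdw(cx)
        assert len(records) == 1
        assert records[0].energy == pytest.approx(-0.086)

    def test_closed_form_at_twice_rmin(self):
        # (1/2)^12 - 2*(1/2)^6 = -0.030762
        rmin, eps = 3.0, 0.2
        assert lj_energy(2 * rmin, rmin, eps) == pytest.approx(
            eps * ((0.5) ** 12 - 2 * (0.5) ** 6))
        assert lj_energy(2 * rmin, rmin, eps) == pytest.approx(-0.031 * eps,
                                                               rel=0.01)

    def test_clash_clamp(self):
        rmin, eps = 3.6, 0.1
        clamped = lj_energy(0.1, rmin, eps)
        assert clamped == lj_energy(0.7 * rmin, rmin, eps)
        assert np.isfinite(clamped)

    def test_total_matches_brute_force_sum(self, default_complex):
        grid = compute_vdw(default_complex, method="grid")
        brute = compute_vdw(default_complex, method="brute")
        assert [r.key() for r in grid] == [r.key() for r in brute]
        assert sum(r.energy for r in grid) == pytest.approx(
            sum(r.energy for r in brute), abs=1e-12)

    def test_attractive_tail_beyond_minimum(self):
        assert lj_energy(4.5, 3.8, 0.1) < 0


class TestInvariants:
    def test_detection_symmetric_under_chain_swap(self, default_complex):
        fwd = detect_all(default_complex)
        rev = detect_all(default_complex.swapped())
        assert sorted(r.key() for r in fwd) == sorted(r.key() for r in rev)
        assert sum(r.energy for r in fwd) == pytest.approx(
            sum(r.energy for r in rev))

    def test_grid_equals_brute_force_on_large_fixture(self):
        # ~1,800 atoms across both chains
        cx = toy_complex(DimerSpec(n_residues=150, n_planted_hbonds=20,
                                   n_planted_saltbridges=10,
                                   interface_contact_fraction=0.8,
                                   polarity_target="A", seed=5))
        assert len(cx.atoms()) <= 2000
        for detector in (detect_hbonds, detect_electrostatics, compute_vdw):
            grid = detector(cx, method="grid")
            brute = detector(cx, method="brute")
            assert [r.key() for r in grid] == [r.key() for r in brute]
            np.testing.assert_array_equal(
                [r.energy for r in grid], [r.energy for r in brute])

    @given(st.floats(min_value=2.5, max_value=3.5),
           st.floats(min_value=3.0, max_value=6.0),
           st.floats(min_value=4.0, max_value=8.0))
    @settings(deadline=None, max_examples=15, derandomize=True)
    def test_shrinking_cutoffs_never_adds_records(self, hb, el, vw):
        cx = toy_complex(DimerSpec(n_residues=8, n_planted_hbonds=2,
                                   n_planted_saltbridges=1,
                                   interface_contact_fraction=0.5,
                                   polarity_target="A", seed=9))
        full = detect_all(cx)
        smaller = detect_all(cx, hbond_cutoff=hb, elec_cutoff=el,
                             vdw_cutoff=vw)
        assert {r.key() for r in smaller} <= {r.key() for r in full}
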