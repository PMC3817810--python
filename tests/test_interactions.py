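import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prorigid.structure_io import Atom, MolecularStructure, build_ideal_helix
from prorigid.interactions import (
    HBondCriteria,
    HydrogenBond,
    HydrophobicInteraction,
    classify_hbond_configurations,
    detect_hbonds,
    detect_hydrophobics_legacy,
    detect_hydrophobics_lj,
    filter_by_energy,
    infer_covalent_bonds,
    lj_energy,
    mayo_energy,
)


def _atom(serial, name, element, resnum, pos, chain="A", resname="ALA"):
    return Atom(serial, name, element, resname, resnum, chain, np.array(pos))


class TestCovalentBonds:
    def test_ethane_bond_census(self, ethane_bonds):
        assert len(ethane_bonds) == 7
        cc = [b for b in ethane_bonds
              if {b.atom_a.element, b.atom_b.element} == {"C"}]
        assert len(cc) == 1 and cc[0].rotatable

    def test_peptide_bond_locked(self, helix18_bonds):
        peptide = [b for b in helix18_bonds if b.kind == "peptide"]
        assert len(peptide) == 17
        assert not any(b.rotatable for b in peptide)

    def test_carbonyl_double_bond_locked(self, helix18_bonds):
        doubles = [b for b in helix18_bonds if b.kind == "double"]
        assert len(doubles) == 18
        assert all({b.atom_a.name, b.atom_b.name} == {"C", "O"}
                   for b in doubles)

    def test_distant_atoms_not_bonded(self):
        st_ = MolecularStructure([
            _atom(1, "C1", "C", 1, [0, 0, 0]),
            _atom(2, "C2", "C", 2, [10, 0, 0]),
        ], "pair")
        assert infer_covalent_bonds(st_) == []


class TestHBondDetection:
    def test_helix_has_14_i_to_i_plus_4_bonds(self, helix18_hbonds):
        assert len(helix18_hbonds) == 14
        for hb in helix18_hbonds:
            assert hb.donor.name == "N" and hb.acceptor.name == "O"
            assert hb.donor.residue_number - hb.acceptor.residue_number == 4

    def test_helix_energies_within_reported_range(self, helix18_hbonds):
        for hb in helix18_hbonds:
            assert -7.0 <= hb.energy <= -2.0

    def test_distance_criterion_rejects(self):
        # N-H pointing at an O 5 Å away: geometry fine, distance too large
        atoms = [
            _atom(1, "N", "N", 1, [0, 0, 0]),
            _atom(2, "H", "H", 1, [1.0, 0, 0]),
            _atom(3, "CA", "C", 1, [-0.8, 1.2, 0]),
            _atom(4, "O", "O", 5, [5.0, 0, 0]),
            _atom(5, "C", "C", 5, [5.8, 1.0, 0]),
        ]
        st_ = MolecularStructure(atoms, "far")
        assert detect_hbonds(st_, infer_covalent_bonds(st_)) == []

    def test_apolar_structure_has_no_hbonds(self, ethane, ethane_bonds):
        assert detect_hbonds(ethane, ethane_bonds) == []

    def test_lone_dipeptide_has_no_hbonds(self):
        di = build_ideal_helix(2)
        assert detect_hbonds(di, infer_covalent_bonds(di)) == []

    def test_bad_criteria_rejected(self, helix18, helix18_bonds):
        with pytest.raises(ValueError):
            detect_hbonds(helix18, helix18_bonds,
                          HBondCriteria(d_DA_max=-1.0))


class TestMayoEnergy:
    def _hb(self, d, theta, phi, donor="sp3", acceptor="sp3", gamma=None):
        return HydrogenBond(
            donor=None, hydrogen=None, acceptor=None, acceptor_bases=[],
            d_HA=d - 1.0, d_DA=d, theta=theta, phi=phi,
            gamma=phi if gamma is None else gamma,
            donor_hybrid=donor, acceptor_hybrid=acceptor,
        )

    def test_ideal_sp3_sp3_geometry_gives_well_depth(self):
        e = mayo_energy(self._hb(2.8, 180.0, 109.5))
        assert e == pytest.approx(-8.0, abs=1e-6)

    def test_vanishes_at_long_range(self):
        assert mayo_energy(self._hb(50.0, 180.0, 109.5)) == \
            pytest.approx(0.0, abs=1e-6)

    def test_right_angle_theta_gives_zero(self):
        assert mayo_energy(self._hb(2.8, 90.0, 109.5)) == pytest.approx(0.0)

    def test_zero_distance_error(self):
        with pytest.raises(ValueError):
            mayo_energy(self._hb(0.0, 180.0, 109.5))

    def test_well_shape(self):
        # minimum near d0, monotonic decay to zero beyond it
        energies = [mayo_energy(self._hb(d, 180.0, 109.5))
                    for d in np.arange(2.7, 6.0, 0.05)]
        i_min = int(np.argmin(energies))
        d_min = 2.7 + 0.05 * i_min
        assert abs(d_min - 2.8) < 0.1
        tail = energies[i_min:]
        assert all(b >= a - 1e-12 for a, b in zip(tail, tail[1:]))
        assert tail[-1] > -0.05


class TestLennardJones:
    def test_zero_crossing_at_sigma(self):
        assert lj_energy(3.4, 0.12, 3.4) == pytest.approx(0.0, abs=1e-9)

    def test_minimum_at_rmin(self):
        sigma, eps = 3.4, 0.12
        assert lj_energy(2 ** (1 / 6) * sigma, eps, sigma) == \
            pytest.approx(-eps, abs=1e-9)

    def test_zero_epsilon(self):
        assert lj_energy(5.0, 0.0, 3.4) == 0.0

    def test_invalid_distance(self):
        with pytest.raises(ValueError):
            lj_energy(0.0, 0.1, 3.4)

    @given(st.floats(min_value=2.0, max_value=10.0),
           st.floats(min_value=0.01, max_value=0.5),
           st.floats(min_value=2.5, max_value=4.0))
    @settings(max_examples=50, derandomize=True)
    def test_sign_structure(self, r, eps, sigma):
        v = lj_energy(r, eps, sigma)
        if r > sigma:
            assert -eps - 1e-9 <= v <= 0.0
        else:
            assert v >= -1e-12


class TestHydrophobicDetection:
    def test_helix_has_no_legacy_interactions(self, helix18_legacy):
        assert helix18_legacy == []

    def test_legacy_contact_pair_detected(self):
        # two CB-like carbons of different residues at vdW sum + 0.2 Å
        atoms = [
            _atom(1, "CB", "C", 1, [0, 0, 0]),
            _atom(2, "CB", "C", 5, [1.7 + 1.7 + 0.2, 0, 0]),
        ]
        st_ = MolecularStructure(atoms, "cbpair")
        found = detect_hydrophobics_legacy(st_, [])
        assert len(found) == 1
        assert math.isnan(found[0].energy)

    def test_legacy_ignores_non_cs_elements(self):
        atoms = [
            _atom(1, "CB", "C", 1, [0, 0, 0]),
            _atom(2, "N", "N", 5, [3.0, 0, 0]),
        ]
        st_ = MolecularStructure(atoms, "cn")
        assert detect_hydrophobics_legacy(st_, []) == []

    def test_helix_lj_energies(self, helix18_lj):
        assert len(helix18_lj) > 0
        in_band = [p for p in helix18_lj if -0.20 <= p.energy <= -0.15]
        assert in_band

    def test_lj_excludes_covalent_and_geminal_pairs(self, helix18,
                                                    helix18_bonds,
                                                    helix18_lj):
        bonded = {frozenset((b.atom_a.serial, b.atom_b.serial))
                  for b in helix18_bonds}
        for p in helix18_lj:
            key = frozenset((p.atom_a.serial, p.atom_b.serial))
            assert key not in bonded
            assert p.atom_a.residue_key != p.atom_b.residue_key

    def test_lj_respects_distance_cap(self, helix18, helix18_bonds):
        close = detect_hydrophobics_lj(helix18, helix18_bonds, r_max=4.0)
        assert all(p.r <= 4.0 for p in close)
        wide = detect_hydrophobics_lj(helix18, helix18_bonds, r_max=6.0)
        assert len(wide) > len(close)

    def test_lj_detection_invariant_to_atom_order(self, helix18,
                                                  helix18_bonds,
                                                  helix18_lj):
        reversed_structure = MolecularStructure(
            list(reversed(helix18.atoms)), "rev")
        again = detect_hydrophobics_lj(reversed_structure, helix18_bonds)
        key = lambda p: tuple(sorted((p.atom_a.serial, p.atom_b.serial)))
        assert sorted(map(key, again)) == sorted(map(key, helix18_lj))

    def test_invalid_r_max(self, helix18, helix18_bonds):
        with pytest.raises(ValueError):
            detect_hydrophobics_lj(helix18, helix18_bonds, r_max=0.0)


class TestEnergyFilter:
    def _fake(self, energies):
        return [HydrophobicInteraction(None, None, r=3.0, energy=e)
                for e in energies]

    def test_split(self):
        kept, excluded = filter_by_energy(self._fake([-2.0, -1.0]), -1.5)
        assert [i.energy for i in kept] == [-2.0]
        assert [i.energy for i in excluded] == [-1.0]

    def test_zero_cutoff_keeps_everything_attractive(self):
        kept, _ = filter_by_energy(self._fake([-2.0, -0.1, 0.0]), 0.0)
        assert len(kept) == 3

    def test_empty(self):
        assert filter_by_energy([], -1.0) == ([], [])

    def test_sentinel_rejected(self):
        with pytest.raises(ValueError):
            filter_by_energy(self._fake([math.nan]), -1.0)

    def test_cutoff_monotonicity(self, helix18_lj):
        cuts = [-0.2, -0.15, -0.1, -0.05, 0.0]
        kept_sets = [
            {id(i) for i in filter_by_energy(helix18_lj, c)[0]}
            for c in cuts
        ]
        for tighter, looser in zip(kept_sets, kept_sets[1:]):
            assert tighter <= looser


class TestConfigurationCensus:
    def test_helix_is_all_non_furcated(self, helix18_hbonds, helix18_bonds):
        census = classify_hbond_configurations(helix18_hbonds, helix18_bonds)
        assert census.total == 14
        assert census.counts == {"non_furcated": 14}
        assert census.fractions["non_furcated"] == 1.0

    def test_bifurcated_donor(self):
        # one N-H pointing between two carbonyl oxygens
        atoms = [
            _atom(1, "N", "N", 1, [0, 0, 0]),
            _atom(2, "H", "H", 1, [1.0, 0, 0]),
            _atom(3, "CA", "C", 1, [-0.8, 1.2, 0]),
            _atom(4, "O", "O", 5, [2.9, 0.9, 0]),
            _atom(5, "C", "C", 5, [3.7, 1.8, 0]),
            _atom(6, "O", "O", 7, [2.9, -0.9, 0]),
            _atom(7, "C", "C", 7, [3.7, -1.8, 0]),
        ]
        st_ = MolecularStructure(atoms, "bif")
        bonds = infer_covalent_bonds(st_)
        hbs = detect_hbonds(st_, bonds)
        assert len(hbs) == 2
        census = classify_hbond_configurations(hbs, bonds)
        assert census.counts.get("furcated_donor(2)") == 2

    def test_multi_base_acceptor(self):
        # hydroxyl O acceptor bridged between two carbons
        atoms = [
            _atom(1, "N", "N", 1, [0, 0, 0]),
            _atom(2, "H", "H", 1, [1.0, 0, 0]),
            _atom(3, "CA", "C", 1, [-0.8, 1.2, 0]),
            _atom(4, "OG", "O", 5, [2.9, 0, 0], resname="SER"),
            _atom(5, "CB", "C", 5, [3.6, 1.2, 0], resname="SER"),
            _atom(6, "CG", "C", 5, [3.6, -1.2, 0], resname="SER"),
        ]
        st_ = MolecularStructure(atoms, "mba")
        bonds = infer_covalent_bonds(st_)
        hbs = detect_hbonds(st_, bonds)
        assert len(hbs) == 1
        census = classify_hbond_configurations(hbs, bonds)
        assert census.counts.get("multi_base_acceptor") == 1
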