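"""Hydrogen-bond detection, classification and positional conservation."""

import numpy as np
import pytest

from conftest import brute_force_hbonds, random_rotation
from pdzkit import synth
from pdzkit.hbonds import (ProtonationError, assign_ligand_positions,
                           conserved_positions, detect_hbonds, fingerprint)
from pdzkit.io import AtomRecord, EmptyInputError, ResidueRecord, StructureModel


def triple_model(d_da: float, theta_deg: float, donor_backbone=True,
                 acceptor_backbone=True) -> StructureModel:
    """Minimal two-chain model with one donor-H...acceptor geometry at the
    requested distance and angle."""
    n = np.zeros(3)
    h = np.array([1.0, 0.0, 0.0])
    # place acceptor at distance d_da from N with the prescribed D-H-A angle
    phi = np.radians(180.0 - theta_deg)  # rotate about H
    direction = np.array([np.cos(phi), np.sin(phi), 0.0])
    # solve |N + t*dir_from_h - ...|: acceptor lies along the ray from H
    # D-H-A angle is the angle at H between (N-H) and (A-H)
    t = _solve_da(d_da, theta_deg)
    a = h + t * direction
    donor_name = "N" if donor_backbone else "NZ"
    acc_name = "O" if acceptor_backbone else "OG"
    prot = ResidueRecord("A", 1, "LEU", [
        AtomRecord(donor_name, "N", n, is_backbone=donor_backbone),
        AtomRecord("H", "H", h, is_backbone=donor_backbone),
        AtomRecord("CA", "C", np.array([-1.0, 1.0, 0.0]), is_backbone=True),
    ])
    lig = ResidueRecord("B", 1, "VAL", [
        AtomRecord(acc_name, "O", a, is_backbone=acceptor_backbone),
        AtomRecord("CA", "C", a + np.array([0.0, 0.0, 8.0]), is_backbone=True),
    ])
    return StructureModel(0, {"A": [prot], "B": [lig]})


def _solve_da(d_da: float, theta_deg: float) -> float:
    """Distance H->A giving donor-acceptor distance d_da at angle theta
    (donor at origin, H at distance 1)."""
    # law of cosines in triangle D-H-A with DH = 1, angle at H = theta
    th = np.radians(theta_deg)
    # d_da^2 = 1 + t^2 - 2 t cos(theta)
    disc = np.cos(th) ** 2 - (1.0 - d_da ** 2)
    return np.cos(th) + np.sqrt(disc)


class TestLigandPositions:
    def test_ten_residue_ligand_counts_back_from_zero(self):
        model = synth.gen_toy_complex(ligand_seq="DTKNYKQTSV", planted_positions={0})
        posmap = assign_ligand_positions(model, "B")
        assert sorted(posmap.position_of.values()) == list(range(-9, 1))

    def test_single_residue_ligand(self):
        model = synth.gen_toy_complex(ligand_seq="V", planted_positions={0})
        assert list(assign_ligand_positions(model, "B").position_of.values()) == [0]

    def test_missing_chain_raises(self):
        model = synth.gen_toy_complex()
        with pytest.raises(KeyError):
            assign_ligand_positions(model, "Z")


class TestDetection:
    @pytest.mark.parametrize("d_da, theta, expect", [
        (2.9, 165.0, 1),   # inside both cutoffs
        (3.8, 165.0, 0),   # beyond 3.7 Å
        (2.9, 100.0, 0),   # below 120°
        (3.65, 125.0, 1),  # near both cutoffs, inside
    ])
    def test_cutoff_geometry(self, d_da, theta, expect):
        bonds = detect_hbonds(triple_model(d_da, theta), "A", "B")
        assert len(bonds) == expect
        if expect:
            assert bonds[0].d_DA == pytest.approx(d_da, abs=1e-6)
            assert bonds[0].theta_DHA == pytest.approx(theta, abs=1e-6)

    @pytest.mark.parametrize("donor_bb, acc_bb, expected", [
        (True, True, "bb-bb"), (True, False, "bb-sc"),
        (False, True, "sc-bb"), (False, False, "sc-sc"),
    ])
    def test_bond_class_partition(self, donor_bb, acc_bb, expected):
        bonds = detect_hbonds(triple_model(2.9, 170.0, donor_bb, acc_bb), "A", "B")
        assert len(bonds) == 1 and bonds[0].bond_class == expected

    def test_no_hydrogens_raises_protonation_error(self):
        prot = ResidueRecord("A", 1, "LEU", [AtomRecord("N", "N", np.zeros(3))])
        lig = ResidueRecord("B", 1, "VAL", [AtomRecord("O", "O", np.array([2.9, 0, 0]))])
        model = StructureModel(0, {"A": [prot], "B": [lig]})
        with pytest.raises(ProtonationError, match="hydrogens"):
            detect_hbonds(model, "A", "B")

    def test_planted_positions_recovered_exactly(self):
        for seed in range(20):
            planted = {0, -2} if seed % 2 else {0, -1, -3}
            model = synth.gen_toy_complex(ligand_seq="KQTSV",
                                          planted_positions=planted, seed=seed)
            found = {b.ligand_position for b in detect_hbonds(model, "A", "B")}
            assert found == planted

    def test_rigid_transform_invariance(self, rng):
        model = synth.gen_toy_complex(planted_positions={0, -2, -4},
                                      ligand_seq="YKQTSV", seed=9)
        before = {(b.donor, b.hydrogen, b.acceptor) for b in detect_hbonds(model, "A", "B")}
        moved = model.transformed(random_rotation(rng), rng.normal(scale=50.0, size=3))
        after = {(b.donor, b.hydrogen, b.acceptor) for b in detect_hbonds(moved, "A", "B")}
        assert before == after and len(before) == 3

    def test_matches_brute_force_oracle(self, rng):
        """KD-tree accelerated detection = exhaustive triple enumeration."""
        for seed in range(10):
            model = synth.gen_toy_complex(
                ligand_seq="DTKNYKQTSV",
                planted_positions={0, -2, -int(rng.integers(3, 9))}, seed=seed)
            got = {(b.donor.chain, b.donor.resseq, b.donor.atom_name,
                    b.hydrogen.atom_name, b.acceptor.chain, b.acceptor.resseq,
                    b.acceptor.atom_name)
                   for b in detect_hbonds(model, "A", "B")}
            assert got == brute_force_hbonds(model, "A", "B")


class TestFingerprint:
    def test_planted_fingerprint_counts(self):
        model = synth.gen_toy_complex(planted_positions={0, -2}, seed=0)
        fp = fingerprint(model, "A", "B")
        assert fp.positions() == {0, -2}
        assert sum(fp.bonds_by_position[0].values()) == 1

    def test_no_contact_complex_empty(self):
        model = synth.gen_toy_complex(planted_positions=set(), seed=0)
        fp = fingerprint(model, "A", "B")
        assert fp.positions() == set()

    def test_duplicate_bonds_kept_as_multiset(self):
        # two acceptors on the same ligand residue within range of one donor
        base = triple_model(2.9, 170.0)
        extra = AtomRecord("OXT", "O", base.chain("B")[0].atom("O").coords
                           + np.array([0.0, 0.35, 0.0]), is_backbone=True)
        base.chain("B")[0].atoms.append(extra)
        fp = fingerprint(base, "A", "B")
        assert sum(fp.bonds_by_position[0].values()) == 2


class TestConservation:
    def test_planted_conservation_across_complexes(self):
        fps = []
        extras = [-1, -3, -4, -1]
        for seed, extra in enumerate(extras):
            model = synth.gen_toy_complex(ligand_seq="YKQTSV",
                                          planted_positions={0, -2, extra}, seed=seed)
            fps.append(fingerprint(model, "A", "B", complex_id=f"c{seed}"))
        assert conserved_positions(fps) == {0, -2}

    def test_position_missing_in_one_complex_excluded(self):
        a = fingerprint(synth.gen_toy_complex(planted_positions={0, -2}), "A", "B")
        b = fingerprint(synth.gen_toy_complex(planted_positions={0}), "A", "B")
        assert conserved_positions([a, b]) == {0}

    def test_disjoint_fingerprints_empty(self):
        a = fingerprint(synth.gen_toy_complex(planted_positions={0}), "A", "B")
        b = fingerprint(synth.gen_toy_complex(planted_positions={-1}), "A", "B")
        assert conserved_positions([a, b]) == set()

    def test_fewer_than_two_fingerprints_rejected(self):
        a = fingerprint(synth.gen_toy_complex(planted_positions={0}), "A", "B")
        with pytest.raises(EmptyInputError):
            conserved_positions([a])
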