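"""Geometric hydrogen-bond detection and per-ligand-position fingerprints.

A hydrogen bond is accepted when the heavy-atom donor-acceptor distance is at
most 3.7 Å and the donor-hydrogen-acceptor angle is at least 120 deg (180 deg
= linear). Donors are N/O/S heavy atoms carrying at least one hydrogen within
1.25 Å; acceptors are N/O heavy atoms. Only intermolecular bonds between the
designated protein and ligand chains are reported.

Ligand residues are numbered from the C-terminus: the last residue is
position 0, the one before -1, and so on — the convention used to describe
PDZ-binding motifs, whose -2 position discriminates the three motif classes.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .io import EmptyInputError, ResidueRecord, StructureModel

__all__ = [
    "AtomRef", "HBond", "LigandPositionMap", "BondFingerprint",
    "ProtonationError", "assign_ligand_positions", "detect_hbonds",
    "fingerprint", "conserved_positions", "add_backbone_amide_hydrogens",
]

DONOR_ELEMENTS = {"N", "O", "S"}   # sulfur as donor covers Cys/Met chemistry
ACCEPTOR_ELEMENTS = {"N", "O"}
H_BOND_LENGTH = 1.25  # Å: a hydrogen belongs to the nearest heavy atom within this


class ProtonationError(ValueError):
    """Raised when H-bond detection is asked to run on a structure without
    explicit hydrogens."""


@dataclass(frozen=True)
class AtomRef:
    chain: str
    resseq: int
    resname: str
    atom_name: str

    @property
    def label(self) -> str:
        from .io import THREE_TO_ONE
        return f"{THREE_TO_ONE.get(self.resname, 'X')}{self.resseq}"


@dataclass(frozen=True)
class HBond:
    donor: AtomRef
    hydrogen: AtomRef
    acceptor: AtomRef
    d_DA: float
    theta_DHA: float
    bond_class: str          # bb-bb | bb-sc | sc-bb | sc-sc (donor side first)
    ligand_position: int


@dataclass
class LigandPositionMap:
    ligand_chain: str
    position_of: dict[int, int]  # resseq -> non-positive position


@dataclass
class BondFingerprint:
    """Hydrogen bonds of one complex, grouped by ligand position.

    Each position maps to a multiset of (protein residue label, bond class)
    pairs; repeated bonds from the same residue are kept.
    """

    complex_id: str
    bonds_by_position: dict[int, Counter] = field(default_factory=dict)

    def positions(self) -> set[int]:
        return {p for p, c in self.bonds_by_position.items() if sum(c.values()) > 0}


def assign_ligand_positions(model: StructureModel, ligand_chain: str) -> LigandPositionMap:
    """Number ligand residues from the C-terminus: last residue = 0, then
    -1, -2, ... toward the N-terminus."""
    residues = model.chain(ligand_chain)
    if not residues:
        raise KeyError(f"ligand chain {ligand_chain!r} has no residues")
    n = len(residues)
    return LigandPositionMap(
        ligand_chain=ligand_chain,
        position_of={res.resseq: i - (n - 1) for i, res in enumerate(residues)},
    )


def _collect(residues: list[ResidueRecord]):
    """Flatten a chain into donor (heavy, hydrogen) pairs and acceptor atoms."""
    heavy, hydro = [], []
    for res in residues:
        for atom in res.atoms:
            (heavy if atom.is_heavy else hydro).append((res, atom))
    donors = []  # (res, heavy_atom, res_h, h_atom)
    if hydro and heavy:
        hcoords = np.array([a.coords for _, a in heavy])
        tree = cKDTree(hcoords)
        for res_h, h in hydro:
            dist, j = tree.query(h.coords)
            if dist <= H_BOND_LENGTH:
                res_d, d = heavy[j]
                if d.element in DONOR_ELEMENTS:
                    donors.append((res_d, d, res_h, h))
    acceptors = [(res, a) for res, a in heavy if a.element in ACCEPTOR_ELEMENTS]
    return donors, acceptors


def _angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle at b (degrees) of the triple a-b-c."""
    u, v = a - b, c - b
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def _bond_class(donor_atom, acceptor_atom) -> str:
    d = "bb" if donor_atom.is_backbone else "sc"
    a = "bb" if acceptor_atom.is_backbone else "sc"
    return f"{d}-{a}"


def detect_hbonds(model: StructureModel, protein_chain: str, ligand_chain: str,
                  d_cut: float = 3.7, theta_cut: float = 120.0) -> list[HBond]:
    """All intermolecular hydrogen bonds between the two chains.

    Both directions are scanned (protein donor -> ligand acceptor and ligand
    donor -> protein acceptor). Requires explicit hydrogens: a structure with
    none raises ProtonationError rather than silently returning nothing.
    """
    prot = model.chain(protein_chain)
    lig = model.chain(ligand_chain)
    if not any(a.is_hydrogen for res in (*prot, *lig) for a in res.atoms):
        raise ProtonationError(
            "structure has no hydrogens on the selected chains; geometric "
            "H-bond detection needs explicit hydrogens (protonate upstream)"
        )
    posmap = assign_ligand_positions(model, ligand_chain)

    bonds: list[HBond] = []
    for donor_side, acceptor_side, donors_are_protein in (
        (prot, lig, True), (lig, prot, False),
    ):
        donors, _ = _collect(donor_side)
        _, acceptors = _collect(acceptor_side)
        if not donors or not acceptors:
            continue
        acc_coords = np.array([a.coords for _, a in acceptors])
        tree = cKDTree(acc_coords)
        for res_d, d, res_h, h in donors:
            for j in tree.query_ball_point(d.coords, r=d_cut):
                res_a, a = acceptors[j]
                d_da = float(np.linalg.norm(d.coords - a.coords))
                theta = _angle_deg(d.coords, h.coords, a.coords)
                if d_da <= d_cut and theta >= theta_cut:
                    lig_res = res_a if donors_are_protein else res_d
                    bonds.append(HBond(
                        donor=AtomRef(res_d.chain_id, res_d.resseq, res_d.resname, d.atom_name),
                        hydrogen=AtomRef(res_h.chain_id, res_h.resseq, res_h.resname, h.atom_name),
                        acceptor=AtomRef(res_a.chain_id, res_a.resseq, res_a.resname, a.atom_name),
                        d_DA=d_da,
                        theta_DHA=theta,
                        bond_class=_bond_class(d, a),
                        ligand_position=posmap.position_of[lig_res.resseq],
                    ))
    return bonds


def fingerprint(model: StructureModel, protein_chain: str, ligand_chain: str,
                complex_id: str = "", d_cut: float = 3.7,
                theta_cut: float = 120.0) -> BondFingerprint:
    """Group the detected bonds by ligand position, recording for each the
    PDZ-side residue label and the bond class (duplicates kept)."""
    bonds = detect_hbonds(model, protein_chain, ligand_chain, d_cut, theta_cut)
    fp = BondFingerprint(complex_id=complex_id or f"model{model.model_id}")
    for b in bonds:
        prot_ref = b.donor if b.donor.chain == protein_chain else b.acceptor
        fp.bonds_by_position.setdefault(b.ligand_position, Counter())[
            (prot_ref.label, b.bond_class)
        ] += 1
    return fp


def conserved_positions(fps: list[BondFingerprint]) -> set[int]:
    """Ligand positions that carry at least one hydrogen bond in every
    fingerprint — conservation across complexes."""
    if len(fps) < 2:
        raise EmptyInputError("conservation needs at least two fingerprints")
    out = fps[0].positions()
    for fp in fps[1:]:
        out &= fp.positions()
    return out


def add_backbone_amide_hydrogens(model: StructureModel,
                                 direction: np.ndarray = np.array([0.0, 0.0, -1.0]),
                                 bond_length: float = 1.0) -> StructureModel:
    """Attach an idealised amide hydrogen to every backbone N lacking one.

    Fixture convenience for synthetic structures only: the hydrogen is placed
    along a fixed direction, not by peptide-plane geometry, so this must not
    be used on real complexes.
    """
    direction = np.asarray(direction, float)
    direction = direction / np.linalg.norm(direction)
    from .io import AtomRecord
    for residues in model.chains.values():
        for res in residues:
            names = {a.atom_name for a in res.atoms}
            if "N" in names and not any(a.is_hydrogen and a.is_backbone for a in res.atoms):
                n = res.atom("N")
                h = AtomRecord("H", "H", n.coords + bond_length * direction,
                               is_backbone=True)
                res.atoms.append(h)
    return model
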