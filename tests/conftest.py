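"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the spatial indexing used by the package:
H-bond enumeration loops over every donor-hydrogen x acceptor triple, and the
triplet-angle oracle works from a full pairwise distance matrix.
"""

from __future__ import annotations

import numpy as np
import pytest

from pdzkit.io import StructureModel
from pdzkit.tetra import water_oxygen_coords


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix via QR of a Gaussian matrix."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


def brute_force_hbonds(model: StructureModel, protein_chain: str,
                       ligand_chain: str, d_cut: float = 3.7,
                       theta_cut: float = 120.0) -> set[tuple]:
    """All intermolecular H-bonds by exhaustive triple enumeration.

    Returns a set of (donor chain, donor resseq, donor atom, hydrogen atom,
    acceptor chain, acceptor resseq, acceptor atom) keys.
    """
    sides = {cid: [(res, a) for res in model.chain(cid) for a in res.atoms]
             for cid in (protein_chain, ligand_chain)}

    def donors(cid):
        atoms = sides[cid]
        heavy = [(r, a) for r, a in atoms if a.is_heavy]
        out = []
        for res_h, h in atoms:
            if h.is_heavy:
                continue
            dists = [np.linalg.norm(h.coords - a.coords) for _, a in heavy]
            if not dists:
                continue
            j = int(np.argmin(dists))
            if dists[j] <= 1.25 and heavy[j][1].element in ("N", "O", "S"):
                out.append((heavy[j][0], heavy[j][1], res_h, h))
        return out

    def acceptors(cid):
        return [(r, a) for r, a in sides[cid] if a.is_heavy and a.element in ("N", "O")]

    found = set()
    for d_side, a_side in ((protein_chain, ligand_chain), (ligand_chain, protein_chain)):
        for res_d, d, res_h, h in donors(d_side):
            for res_a, a in acceptors(a_side):
                d_da = np.linalg.norm(d.coords - a.coords)
                u, v = d.coords - h.coords, a.coords - h.coords
                theta = np.degrees(np.arccos(np.clip(
                    np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)), -1, 1)))
                if d_da <= d_cut and theta >= theta_cut:
                    found.add((res_d.chain_id, res_d.resseq, d.atom_name, h.atom_name,
                               res_a.chain_id, res_a.resseq, a.atom_name))
    return found


def brute_force_triplet_angles(frame: StructureModel, shell_indices: np.ndarray,
                               r_nb: float = 3.4) -> np.ndarray:
    """Triplet angles via a full O(n^2) distance matrix and explicit loops
    over all neighbour pairs of every shell oxygen — no spatial indexing."""
    waters = water_oxygen_coords(frame)
    box = frame.box

    def mic(v):
        return v if box is None else v - box * np.round(v / box)

    n = waters.shape[0]
    dist = np.empty((n, n))
    for i in range(n):
        dist[i] = np.linalg.norm(mic(waters - waters[i]), axis=1)
    angles = []
    for i in shell_indices:
        nb = [j for j in range(n) if j != i and dist[i, j] <= r_nb]
        for a in range(len(nb)):
            for b in range(a + 1, len(nb)):
                u = mic(waters[nb[a]] - waters[i])
                v = mic(waters[nb[b]] - waters[i])
                c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
                angles.append(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))
    return np.array(angles)
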