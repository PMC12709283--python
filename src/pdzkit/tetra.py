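"""Water triplet-angle (three-body angle) distribution and tetrahedral
fraction around protein sites.

The local structuring of hydration water reports on surface chemistry: water
near small hydrophobic groups retains more tetrahedral order, water near
hydrophilic/charged groups less. For every hydration-shell water oxygen (an
oxygen within ``r_hyd`` = 4.25 Å of a designated heavy probe atom) the angles
it forms with every unordered pair of neighbouring water oxygens (within
``r_nb`` of it, drawn from all waters in the frame) are accumulated; the
tetrahedral water fraction is the share of those angles falling in
[100 deg, 120 deg), the band around the ideal tetrahedral angle of 109.47
deg. Fractions are pooled over the frames of a replica and averaged across
replicas.

Neighbour searches use a k-d tree; with an orthorhombic box present on the
frame, minimum-image distances are used.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .io import EmptyInputError, StructureModel

__all__ = [
    "HydrationShell", "TripletHistogram", "TetrahedralityResult",
    "WATER_RESNAMES", "water_oxygen_coords", "select_hydration_waters",
    "triplet_angles", "histogram_angles", "tetrahedral_fraction",
    "fraction_in_window", "site_tetrahedrality", "resolve_probes",
]

WATER_RESNAMES = {"HOH", "WAT", "SOL", "TIP3", "TIP4", "TIP4P", "TIP5", "SPC"}
# extra-point / virtual-site atom names of 4- and 5-site water models
_VIRTUAL_SITE_NAMES = {"MW", "EPW", "EP", "LP1", "LP2", "M"}

TETRAHEDRAL_ANGLE = float(np.degrees(np.arccos(-1.0 / 3.0)))  # 109.47°


@dataclass
class HydrationShell:
    frame_id: int
    water_indices: np.ndarray     # indices into the frame's water-oxygen array
    r_hyd: float = 4.25


@dataclass
class TripletHistogram:
    """Binned triplet-angle distribution over [0°, 180°]."""

    bin_edges: np.ndarray
    counts: np.ndarray

    @property
    def n_triplets(self) -> int:
        return int(self.counts.sum())


@dataclass
class TetrahedralityResult:
    fraction: float               # pooled over all replicas
    per_replica: list[float]
    mean: float
    sd: float
    window: tuple[float, float] = (100.0, 120.0)
    n_triplets: int = 0


def water_oxygen_coords(frame: StructureModel) -> np.ndarray:
    """Coordinates of all water oxygens in a frame; virtual sites and
    hydrogens are excluded."""
    coords = []
    for residues in frame.chains.values():
        for res in residues:
            if res.resname not in WATER_RESNAMES:
                continue
            for atom in res.atoms:
                if atom.element == "O" and atom.atom_name not in _VIRTUAL_SITE_NAMES:
                    coords.append(atom.coords)
    return np.array(coords) if coords else np.empty((0, 3))


def _tree(coords: np.ndarray, box: np.ndarray | None) -> cKDTree:
    if box is not None:
        return cKDTree(np.mod(coords, box), boxsize=box)
    return cKDTree(coords)


def select_hydration_waters(frame: StructureModel, probe_coords: np.ndarray,
                            r_hyd: float = 4.25) -> HydrationShell:
    """Water oxygens within ``r_hyd`` of at least one probe heavy atom
    (union over probes, no duplicates)."""
    waters = water_oxygen_coords(frame)
    if waters.shape[0] == 0:
        raise EmptyInputError(f"frame {frame.model_id}: no water residues")
    probe_coords = np.atleast_2d(np.asarray(probe_coords, float))
    tree = _tree(waters, frame.box)
    members: set[int] = set()
    for p in probe_coords:
        q = np.mod(p, frame.box) if frame.box is not None else p
        members.update(tree.query_ball_point(q, r=r_hyd))
    return HydrationShell(frame_id=frame.model_id,
                          water_indices=np.array(sorted(members), dtype=int),
                          r_hyd=r_hyd)


def _minimum_image(vec: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    if box is None:
        return vec
    return vec - box * np.round(vec / box)


def triplet_angles(frame: StructureModel, shell: HydrationShell,
                   r_nb: float = 3.4) -> np.ndarray:
    """Angles (degrees) at each shell oxygen formed by every unordered pair
    of its water-oxygen neighbours within ``r_nb``.

    Neighbours are drawn from ALL water oxygens of the frame, not only shell
    members, so oxygens at the shell boundary get complete neighbourhoods.
    """
    if r_nb <= 0:
        raise ValueError(f"r_nb must be positive, got {r_nb}")
    waters = water_oxygen_coords(frame)
    if shell.water_indices.size == 0 or waters.shape[0] < 3:
        return np.empty(0)
    box = frame.box
    tree = _tree(waters, box)
    query = np.mod(waters[shell.water_indices], box) if box is not None else waters[shell.water_indices]
    neighbor_lists = tree.query_ball_point(query, r=r_nb)
    angles: list[np.ndarray] = []
    for center, neighbors in zip(shell.water_indices, neighbor_lists):
        nb = [j for j in neighbors if j != center]
        if len(nb) < 2:
            continue
        vecs = _minimum_image(waters[nb] - waters[center], box)
        norms = np.linalg.norm(vecs, axis=1)
        unit = vecs / norms[:, None]
        cosmat = np.clip(unit @ unit.T, -1.0, 1.0)
        iu, ju = np.triu_indices(len(nb), k=1)
        angles.append(np.degrees(np.arccos(cosmat[iu, ju])))
    return np.concatenate(angles) if angles else np.empty(0)


def histogram_angles(angles: np.ndarray, n_bins: int = 180) -> TripletHistogram:
    """Histogram angles into ``n_bins`` uniform bins over [0°, 180°]."""
    edges = np.linspace(0.0, 180.0, n_bins + 1)
    counts, _ = np.histogram(np.asarray(angles, float), bins=edges)
    return TripletHistogram(bin_edges=edges, counts=counts)


def fraction_in_window(angles: np.ndarray, lo: float = 100.0, hi: float = 120.0) -> float:
    """Share of angles in [lo, hi); 0 for an empty angle list."""
    angles = np.asarray(angles, float)
    if angles.size == 0:
        return 0.0
    return float(np.mean((angles >= lo) & (angles < hi)))


def tetrahedral_fraction(hist: TripletHistogram, lo: float = 100.0,
                         hi: float = 120.0) -> float:
    """Integrate the (normalised) triplet distribution over [lo, hi).

    The window must coincide with histogram bin edges, otherwise the count
    ratio would not equal the integral.
    """
    edges = hist.bin_edges
    tol = 1e-9
    if not (np.any(np.abs(edges - lo) < tol) and np.any(np.abs(edges - hi) < tol)):
        raise ValueError(
            f"window [{lo}, {hi}] must align with histogram bin edges "
            f"(width {edges[1] - edges[0]:.4g}°)"
        )
    total = hist.counts.sum()
    if total == 0:
        return 0.0
    sel = (edges[:-1] >= lo - tol) & (edges[1:] <= hi + tol)
    return float(hist.counts[sel].sum() / total)


def resolve_probes(frame: StructureModel, sites: Sequence[tuple[str, int, str]],
                   probe_mode: str = "parent_heavy") -> np.ndarray:
    """Turn (chain, resseq, atom_name) site selections into probe coordinates.

    probe_mode:
      parent_heavy  — if the named atom is a hydrogen, use its parent heavy
                      atom (nearest heavy atom in the residue); heavy atoms
                      are used as-is. Default: hydration shells are defined
                      relative to heavy atoms even when the site of interest
                      is an amide hydrogen.
      residue_heavy — all heavy atoms of the residue.
      hydrogen      — the named atom itself, whatever its element.
    """
    coords: list[np.ndarray] = []
    for chain_id, resseq, atom_name in sites:
        residues = [r for r in frame.chain(chain_id) if r.resseq == resseq]
        if not residues:
            raise KeyError(f"residue {resseq} not in chain {chain_id!r}")
        res = residues[0]
        if probe_mode == "residue_heavy":
            coords.extend(a.coords for a in res.atoms if a.is_heavy)
            continue
        atom = res.atom(atom_name)
        if probe_mode == "hydrogen" or atom.is_heavy:
            coords.append(atom.coords)
        elif probe_mode == "parent_heavy":
            heavy = [a for a in res.atoms if a.is_heavy]
            if not heavy:
                raise ValueError(f"residue {resseq}: no heavy atoms for parent lookup")
            d = [np.linalg.norm(atom.coords - h.coords) for h in heavy]
            coords.append(heavy[int(np.argmin(d))].coords)
        else:
            raise ValueError(f"unknown probe_mode {probe_mode!r}")
    return np.array(coords)


def site_tetrahedrality(replicas: Sequence[Sequence[StructureModel]],
                        sites: Sequence[tuple[str, int, str]],
                        r_hyd: float = 4.25, r_nb: float = 3.4,
                        lo: float = 100.0, hi: float = 120.0,
                        probe_mode: str = "parent_heavy") -> TetrahedralityResult:
    """Tetrahedral water fraction at a site, per replica and averaged.

    Each replica is a list of frames; within a replica the triplet counts of
    all frames are pooled before the fraction is taken. The reported mean and
    sd (sample sd, 0 for one replica) are across replicas.
    """
    if not replicas or any(len(r) == 0 for r in replicas):
        raise EmptyInputError("each replica needs at least one frame")
    per_replica: list[float] = []
    pooled_in = pooled_total = 0
    for frames in replicas:
        n_in = n_total = 0
        for frame in frames:
            probes = resolve_probes(frame, sites, probe_mode)
            shell = select_hydration_waters(frame, probes, r_hyd)
            angles = triplet_angles(frame, shell, r_nb)
            n_in += int(np.sum((angles >= lo) & (angles < hi)))
            n_total += angles.size
        per_replica.append(n_in / n_total if n_total else 0.0)
        pooled_in += n_in
        pooled_total += n_total
    mean = float(np.mean(per_replica))
    sd = float(np.std(per_replica, ddof=1)) if len(per_replica) > 1 else 0.0
    return TetrahedralityResult(
        fraction=pooled_in / pooled_total if pooled_total else 0.0,
        per_replica=per_replica, mean=mean, sd=sd, window=(lo, hi),
        n_triplets=pooled_total,
    )
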