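"""Synthetic inputs with the statistical and geometric structure each
analysis stage assumes, so the pipeline is testable end to end without
structure-prediction or simulation outputs.

Generators:
  gen_waters        — water-oxygen point configurations: an ice-like
                      tetrahedral network (diamond lattice + Gaussian jitter)
                      or an ideal-gas configuration with a hard minimum
                      separation, plus a probe heavy atom at the box centre.
  gen_pae           — two-chain pAE matrices with controlled interchain error.
  gen_toy_complex   — a toy two-chain complex with hydrogen-bond geometries
                      planted at chosen ligand positions.
  gen_embeddings    — group-structured Gaussian embedding matrices.
  gen_posterior_table — per-site amino-acid posteriors peaked at a target
                      sequence with controlled confidence.

Every generator is deterministic in (parameters, seed).
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import (AtomRecord, PAEMatrix, PosteriorTable, ResidueRecord,
                 StructureModel, AA_ALPHABET, ONE_TO_THREE)

__all__ = ["gen_waters", "gen_pae", "gen_toy_complex", "gen_embeddings",
           "gen_posterior_table", "PAE_MAX"]

PAE_MAX = 31.75          # ColabFold's pAE ceiling
MIN_O_SEP = 2.4          # hard-core O-O separation for the ideal gas, Å
WATER_DENSITY = 0.0312   # default number density of oxygens, Å^-3


class PackingError(RuntimeError):
    """Raised when an ideal-gas configuration cannot be packed at the
    requested density."""


# ---------------------------------------------------------------------------
# Water configurations
# ---------------------------------------------------------------------------

# Diamond-cubic fractional coordinates: fcc + tetrahedral basis offset.
_DIAMOND_FRAC = np.array([
    [0.00, 0.00, 0.00], [0.00, 0.50, 0.50], [0.50, 0.00, 0.50],
    [0.50, 0.50, 0.00], [0.25, 0.25, 0.25], [0.25, 0.75, 0.75],
    [0.75, 0.25, 0.75], [0.75, 0.75, 0.25],
])


def _lattice_points(n: int, a: float) -> tuple[np.ndarray, float]:
    """At least n diamond-lattice points (lattice constant a); returns the
    points sorted by distance from the configuration centre and the box edge."""
    m = 1
    while 8 * m ** 3 < n:
        m += 1
    cells = []
    for i in range(m):
        for j in range(m):
            for k in range(m):
                cells.append((_DIAMOND_FRAC + np.array([i, j, k])) * a)
    pts = np.concatenate(cells)
    centre = pts.mean(axis=0)
    order = np.argsort(np.linalg.norm(pts - centre, axis=1), kind="stable")
    return pts[order[:n]], m * a


def _pack_gas(n: int, box: float, rng: np.random.Generator,
              min_sep: float = MIN_O_SEP, fixed: np.ndarray | None = None,
              max_tries: int = 200) -> np.ndarray:
    """Sequential random insertion with a hard minimum separation, using a
    cell list so packing stays O(n)."""
    cell = min_sep
    ncell = max(1, int(box / cell))
    grid: dict[tuple[int, int, int], list[np.ndarray]] = {}

    def key(p: np.ndarray) -> tuple[int, int, int]:
        return tuple(np.minimum((p / (box / ncell)).astype(int), ncell - 1))

    def ok(p: np.ndarray) -> bool:
        kx, ky, kz = key(p)
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    for q in grid.get(((kx + dx) % ncell, (ky + dy) % ncell,
                                       (kz + dz) % ncell), []):
                        if np.linalg.norm(p - q) < min_sep:
                            return False
        return True

    def put(p: np.ndarray) -> None:
        grid.setdefault(key(p), []).append(p)

    if fixed is not None:
        for p in np.atleast_2d(fixed):
            put(np.asarray(p, float))
    placed: list[np.ndarray] = []
    for _ in range(n):
        for _ in range(max_tries):
            p = rng.uniform(0, box, size=3)
            if ok(p):
                put(p)
                placed.append(p)
                break
        else:
            raise PackingError(
                f"cannot place {n} points with {min_sep} Å separation in a "
                f"{box:.1f} Å box"
            )
    return np.array(placed)


def _waters_model(coords: np.ndarray, probe: np.ndarray | None,
                  model_id: int = 0, box: np.ndarray | None = None) -> StructureModel:
    chains: dict[str, list[ResidueRecord]] = {}
    if probe is not None:
        chains["P"] = [ResidueRecord("P", 1, "PRB",
                                     [AtomRecord("C", "C", probe)])]
    chains["W"] = [
        ResidueRecord("W", i + 1, "HOH", [AtomRecord("O", "O", c)])
        for i, c in enumerate(coords)
    ]
    return StructureModel(model_id=model_id, chains=chains, box=box)


def gen_waters(kind: str, n: int = 216, density: float = WATER_DENSITY,
               jitter: float = 0.1, seed: int = 0, n_frames: int = 1,
               include_probe: bool = True) -> list[StructureModel]:
    """Water-oxygen configurations as one StructureModel per frame.

    kind='tetra_lattice': oxygens on a diamond-cubic (ice-like) network whose
    lattice constant matches ``density``; every nearest-neighbour triplet
    angle is the ideal 109.47 deg at ``jitter`` 0, degraded by isotropic
    Gaussian jitter (sd in Å). kind='ideal_gas': uniformly random positions
    at the same density with a 2.4 Å hard core — no angular order. A probe
    heavy atom sits at the configuration centre so hydration-shell selection
    is exercised; waters overlapping the probe are removed (lattice) or
    avoided (gas).
    """
    if n < 5:
        raise ValueError("need at least 5 waters")
    rng = np.random.default_rng(seed)
    frames: list[StructureModel] = []
    if kind == "tetra_lattice":
        a = (8.0 / density) ** (1.0 / 3.0)
        base, _ = _lattice_points(n + 8, a)
        probe = base.mean(axis=0)
        keep = np.linalg.norm(base - probe, axis=1) >= MIN_O_SEP
        base = base[keep][:n]
        for f in range(n_frames):
            coords = base + rng.normal(0.0, jitter, size=base.shape) if jitter > 0 else base.copy()
            frames.append(_waters_model(coords, probe if include_probe else None, f))
    elif kind == "ideal_gas":
        box = (n / density) ** (1.0 / 3.0)
        probe = np.full(3, box / 2.0)
        for f in range(n_frames):
            coords = _pack_gas(n, box, rng,
                               fixed=probe[None, :] if include_probe else None)
            frames.append(_waters_model(coords, probe if include_probe else None, f))
    else:
        raise ValueError(f"unknown water generator kind {kind!r}")
    return frames


# ---------------------------------------------------------------------------
# pAE matrices
# ---------------------------------------------------------------------------

def gen_pae(n_a: int, n_b: int, pattern: tuple, seed: int = 0,
            intra: float = 2.0) -> PAEMatrix:
    """Two-chain pAE matrix with a controlled interchain block.

    pattern is one of ("constant", c), ("two_level", c1, c2, frac) with a
    fraction ``frac`` of interchain entries at c1 and the rest at c2, or
    ("noisy", mean, sd) with i.i.d. Gaussian interchain entries. Intrachain
    blocks are flat at ``intra`` with a zero diagonal; everything is clipped
    to [0, 31.75].
    """
    if n_a < 1 or n_b < 1:
        raise ValueError("chain lengths must be >= 1")
    rng = np.random.default_rng(seed)
    n = n_a + n_b
    values = np.full((n, n), float(intra))
    np.fill_diagonal(values, 0.0)
    inter_shape_ab, inter_shape_ba = (n_a, n_b), (n_b, n_a)
    kind = pattern[0]
    if kind == "constant":
        c = float(pattern[1])
        if not 0.0 <= c <= PAE_MAX:
            raise ValueError(f"constant level {c} outside [0, {PAE_MAX}]")
        ab = np.full(inter_shape_ab, c)
        ba = np.full(inter_shape_ba, c)
    elif kind == "two_level":
        c1, c2, frac = float(pattern[1]), float(pattern[2]), float(pattern[3])
        for c in (c1, c2):
            if not 0.0 <= c <= PAE_MAX:
                raise ValueError(f"level {c} outside [0, {PAE_MAX}]")
        ab = np.where(rng.random(inter_shape_ab) < frac, c1, c2)
        ba = np.where(rng.random(inter_shape_ba) < frac, c1, c2)
    elif kind == "noisy":
        mean, sd = float(pattern[1]), float(pattern[2])
        ab = rng.normal(mean, sd, inter_shape_ab)
        ba = rng.normal(mean, sd, inter_shape_ba)
    else:
        raise ValueError(f"unknown pAE pattern {kind!r}")
    values[:n_a, n_a:] = ab
    values[n_a:, :n_a] = ba
    values = np.clip(values, 0.0, PAE_MAX)
    chain_of = np.array(["A"] * n_a + ["B"] * n_b)
    return PAEMatrix(values=values, chain_of=chain_of)


# ---------------------------------------------------------------------------
# Toy PDZ-ligand complexes
# ---------------------------------------------------------------------------

_SPACING = 3.5        # Å between consecutive residues along the strand
_PLANT_D_DA = 2.9     # planted donor-acceptor distance: within 3.2 Å margin
_FAR_Z = 8.0          # non-planted ligand plane: violates the 3.7 Å cutoff


def _strand_residue(chain: str, resseq: int, resname: str, x: float,
                    with_h: bool, rng: np.random.Generator,
                    jitter: float, z: float = 0.0) -> ResidueRecord:
    def j() -> np.ndarray:
        return rng.normal(0.0, jitter, 3) if jitter > 0 else np.zeros(3)

    atoms = [
        AtomRecord("N", "N", np.array([x, 0.0, z]) + j(), is_backbone=True),
        AtomRecord("CA", "C", np.array([x + 1.2, 0.8, z]) + j(), is_backbone=True),
        AtomRecord("C", "C", np.array([x + 2.3, 0.0, z]) + j(), is_backbone=True),
        AtomRecord("O", "O", np.array([x + 2.3, -1.2, z]) + j(), is_backbone=True),
    ]
    if with_h:
        atoms.append(AtomRecord("H", "H", atoms[0].coords + np.array([0.0, 0.0, -1.0]),
                                is_backbone=True))
    return ResidueRecord(chain, resseq, resname, atoms)


def gen_toy_complex(pocket_motif: str = "GLGF", ligand_seq: str = "KQTSV",
                    planted_positions: Iterable[int] = (0, -2), seed: int = 0,
                    jitter: float = 0.02) -> StructureModel:
    """Toy two-chain complex with hydrogen bonds planted at chosen ligand
    positions.

    Chain A is an extended "pocket" strand carrying the ``pocket_motif``
    residues (padded with alanines) and backbone amide hydrogens pointing
    toward the ligand. Chain B is the ligand strand, numbered so its last
    residue is position 0. For each planted position the ligand residue's
    carbonyl oxygen is placed 2.9 Å from the facing pocket nitrogen along the
    N-H axis (D-H-A angle 180 deg) — comfortably inside the 3.7 Å / 120 deg
    detection cutoffs; every other ligand polar atom stays >= 8 Å away from
    the pocket, violating the distance cutoff outright. Coordinate jitter is
    kept an order of magnitude below the planted margins so detection never
    sits on a decision boundary.
    """
    planted = set(int(p) for p in planted_positions)
    L = len(ligand_seq)
    if any(p > 0 or p <= -L for p in planted):
        raise ValueError(f"planted positions {sorted(planted)} outside 0..{-(L - 1)}")
    pocket_seq = ("AA" + pocket_motif.upper() + "A" * max(0, L + 2 - len(pocket_motif) - 2))
    n_prot = len(pocket_seq)
    rng = np.random.default_rng(seed)

    protein = [
        _strand_residue("A", i + 1, ONE_TO_THREE.get(aa, "ALA"), i * _SPACING,
                        with_h=True, rng=rng, jitter=jitter)
        for i, aa in enumerate(pocket_seq)
    ]

    ligand: list[ResidueRecord] = []
    for i, aa in enumerate(ligand_seq.upper()):
        pos = i - (L - 1)                         # ligand position (<= 0)
        prot_idx = n_prot - 1 + pos               # facing pocket residue
        if prot_idx < 0:
            raise ValueError("ligand longer than pocket strand; extend pocket_motif padding")
        x = prot_idx * _SPACING
        res = _strand_residue("B", i + 1, ONE_TO_THREE.get(aa, "ALA"), x,
                              with_h=False, rng=rng, jitter=jitter, z=-_FAR_Z)
        if pos in planted:
            # acceptor O on the donor N-H axis of the facing pocket residue
            n_atom = protein[prot_idx].atom("N")
            res.atom("O").coords = n_atom.coords + np.array([0.0, 0.0, -_PLANT_D_DA])
        ligand.append(res)

    model = StructureModel(model_id=0, chains={"A": protein, "B": ligand})
    return model


# ---------------------------------------------------------------------------
# Embeddings and posterior tables
# ---------------------------------------------------------------------------

def gen_embeddings(k_groups: int = 4, n_per_group: int = 12, dims: int = 64,
                   separation: float = 0.0, seed: int = 0
                   ) -> tuple[np.ndarray, list[str], pd.DataFrame]:
    """Gaussian clusters in embedding space, separated along one planted
    direction by ``separation`` noise-sd units between consecutive group
    means. Group 0 is labelled single-celled, the rest multi-celled."""
    if k_groups < 2:
        raise ValueError("need at least two groups")
    rng = np.random.default_rng(seed)
    direction = rng.normal(size=dims)
    direction /= np.linalg.norm(direction)
    rows, ids, groups, cells = [], [], [], []
    for g in range(k_groups):
        X = rng.normal(size=(n_per_group, dims))
        X += (g * separation) * direction
        rows.append(X)
        for i in range(n_per_group):
            ids.append(f"pdz{g}_{i}")
            groups.append(str(g))
            cells.append("single" if g == 0 else "multi")
    labels = pd.DataFrame({"pdz_group": groups, "cellularity": cells}, index=ids)
    return np.concatenate(rows), ids, labels


def gen_posterior_table(seq: str, confidence: float = 0.9,
                        seed: int = 0, alphabet: str = AA_ALPHABET) -> PosteriorTable:
    """Per-site posterior table peaked at ``seq``: the target residue gets
    exactly ``confidence`` and the remaining mass is uniform over the other
    19 letters. Exact placement keeps threshold-boundary behaviour testable
    (e.g. confidence 0.5 sits exactly at the default MAP threshold)."""
    if not 0.05 < confidence <= 1.0:
        raise ValueError("confidence must lie in (0.05, 1]")
    seq = seq.upper()
    idx = {aa: i for i, aa in enumerate(alphabet)}
    probs = np.full((len(seq), len(alphabet)), (1.0 - confidence) / (len(alphabet) - 1))
    for site, aa in enumerate(seq):
        if aa not in idx:
            raise ValueError(f"residue {aa!r} not in alphabet")
        probs[site, :] = (1.0 - confidence) / (len(alphabet) - 1)
        probs[site, idx[aa]] = confidence
    return PosteriorTable(probs=probs, alphabet=alphabet)
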