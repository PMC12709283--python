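"""Domain types and file I/O for structures, pAE matrices, sequences and
posterior tables.

Coordinates and predicted-aligned-error values are in Ångström throughout;
nothing in the package converts units. Structures are plain containers
(chains → residues → atoms); parsing of the PDB format is delegated to
Bio.PDB, with a small fixed-column writer for round-trips and synthetic
fixtures.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.PDB import PDBParser
from Bio.SeqRecord import SeqRecord as _BioSeqRecord
from Bio.Seq import Seq as _BioSeq

__all__ = [
    "AtomRecord",
    "ResidueRecord",
    "StructureModel",
    "PAEMatrix",
    "SequenceRecord",
    "PosteriorTable",
    "FormatError",
    "EmptyInputError",
    "read_structure",
    "write_structure",
    "read_pae",
    "write_pae_json",
    "read_fasta",
    "write_fasta",
    "read_posterior_table",
    "write_posterior_table",
    "AA_ALPHABET",
    "THREE_TO_ONE",
    "ONE_TO_THREE",
]

# Alphabetical one-letter order used for posterior tables unless the caller
# declares another order.
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

# Backbone heavy atoms; terminal carboxylate oxygens count as backbone so that
# C-terminal carboxylate hydrogen bonds classify as backbone-backbone.
BACKBONE_HEAVY = {"N", "CA", "C", "O", "OXT"}

# Two-letter element symbols recognised when inferring the element from the
# atom name (fallback for toy fixtures without element columns).
_TWO_LETTER_ELEMENTS = {
    "CL", "BR", "FE", "ZN", "MG", "MN", "NA", "CA", "CU", "NI", "SE", "CO",
}


class FormatError(ValueError):
    """Raised when an input file cannot be interpreted in its declared format."""


class EmptyInputError(ValueError):
    """Raised when an input is syntactically valid but contains no usable data."""


@dataclass
class AtomRecord:
    """A single atom: name, element symbol and Cartesian coordinates (Å)."""

    atom_name: str
    element: str
    coords: np.ndarray
    is_backbone: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.atom_name!r}: coords must be a finite 3-vector")
        if not self.element:
            raise ValueError(f"atom {self.atom_name!r}: element symbol is empty")
        self.element = self.element.upper()

    @property
    def is_heavy(self) -> bool:
        return self.element != "H"

    @property
    def is_hydrogen(self) -> bool:
        return self.element == "H"


@dataclass
class ResidueRecord:
    """One residue: chain id, author residue number, 3-letter name, atoms."""

    chain_id: str
    resseq: int
    resname: str
    atoms: list[AtomRecord] = field(default_factory=list)
    icode: str = ""

    def __post_init__(self) -> None:
        self.resname = self.resname.upper()
        names = [a.atom_name for a in self.atoms]
        if len(names) != len(set(names)):
            raise ValueError(
                f"residue {self.resname}{self.resseq}: duplicate atom names"
            )

    def atom(self, name: str) -> AtomRecord:
        for a in self.atoms:
            if a.atom_name == name:
                return a
        raise KeyError(f"atom {name!r} not in {self.resname}{self.resseq}")

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.resname, "X")


@dataclass
class StructureModel:
    """One coordinate model (e.g. one trajectory frame): chains of residues.

    ``box`` holds orthorhombic box edge lengths (Å) from a CRYST1 record when
    present; it is used for minimum-image distance computations downstream.
    """

    model_id: int
    chains: dict[str, list[ResidueRecord]]
    box: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.chains:
            raise ValueError("StructureModel requires at least one chain")

    def chain(self, chain_id: str) -> list[ResidueRecord]:
        try:
            return self.chains[chain_id]
        except KeyError:
            raise KeyError(
                f"chain {chain_id!r} not present (have {sorted(self.chains)})"
            ) from None

    def iter_atoms(self) -> Iterable[tuple[ResidueRecord, AtomRecord]]:
        for residues in self.chains.values():
            for res in residues:
                for atom in res.atoms:
                    yield res, atom

    @property
    def n_atoms(self) -> int:
        return sum(1 for _ in self.iter_atoms())

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """Return a copy with ``x -> R x + t`` applied to every atom."""
        rotation = np.asarray(rotation, float)
        translation = np.asarray(translation, float)
        chains: dict[str, list[ResidueRecord]] = {}
        for cid, residues in self.chains.items():
            chains[cid] = [
                ResidueRecord(
                    chain_id=r.chain_id,
                    resseq=r.resseq,
                    resname=r.resname,
                    icode=r.icode,
                    atoms=[
                        AtomRecord(a.atom_name, a.element, rotation @ a.coords + translation,
                                   is_backbone=a.is_backbone)
                        for a in r.atoms
                    ],
                )
                for r in residues
            ]
        return StructureModel(self.model_id, chains, box=None if self.box is None else self.box.copy())


@dataclass
class PAEMatrix:
    """Square predicted-aligned-error matrix (Å) with per-position chain labels."""

    values: np.ndarray
    chain_of: np.ndarray
    plddt: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.chain_of = np.asarray(self.chain_of)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise FormatError(f"pAE matrix must be square, got shape {self.values.shape}")
        if np.any(self.values < 0):
            raise ValueError("pAE values must be non-negative")
        if self.chain_of.shape != (self.values.shape[0],):
            raise ValueError("chain_of length must match matrix dimension")
        if self.plddt is not None:
            self.plddt = np.asarray(self.plddt, dtype=float)
            if self.plddt.shape != (self.values.shape[0],):
                raise ValueError("plddt length must match matrix dimension")
            if np.any((self.plddt < 0) | (self.plddt > 100)):
                raise ValueError("plddt values must lie in [0, 100]")

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class SequenceRecord:
    """A named amino-acid sequence (standard 20 letters plus X)."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        if not self.seq:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.seq) - set(AA_ALPHABET + "X")
        if bad:
            raise ValueError(f"sequence {self.id!r}: invalid letters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class PosteriorTable:
    """Per-site amino-acid posterior probabilities (one row per site).

    ``alphabet`` records the column order; rows are stored normalised.
    """

    probs: np.ndarray
    alphabet: str = AA_ALPHABET
    site_index: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != len(self.alphabet):
            raise ValueError(
                f"posterior table must have {len(self.alphabet)} columns, got {self.probs.shape}"
            )
        if np.any((self.probs < 0) | (self.probs > 1)):
            raise ValueError("posterior probabilities must lie in [0, 1]")
        sums = self.probs.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-3):
            bad = int(np.argmax(np.abs(sums - 1.0)))
            raise ValueError(
                f"site {bad + 1}: probabilities sum to {sums[bad]:.4f} (|sum-1| > 1e-3)"
            )
        self.probs = self.probs / sums[:, None]
        if self.site_index is None:
            self.site_index = np.arange(1, self.probs.shape[0] + 1)
        else:
            self.site_index = np.asarray(self.site_index, dtype=int)

    @property
    def n_sites(self) -> int:
        return self.probs.shape[0]


# ---------------------------------------------------------------------------
# Structures (PDB)
# ---------------------------------------------------------------------------

def _infer_element(atom_name: str) -> str:
    """Element from an atom name: first alphabetic character, with a fixed
    lookup for two-letter elements. Fallback only — real prediction outputs
    populate PDB columns 77-78."""
    stripped = atom_name.strip()
    letters = re.sub(r"[^A-Za-z]", "", stripped)
    if not letters:
        raise FormatError(f"cannot infer element from atom name {atom_name!r}")
    if letters[:2].upper() in _TWO_LETTER_ELEMENTS:
        return letters[:2].upper()
    return letters[0].upper()


def _flag_backbone(residues: list[ResidueRecord]) -> None:
    """Mark backbone atoms in place: the N/CA/C/O/OXT heavy atoms, plus any
    hydrogen whose nearest heavy atom within 1.25 Å is a backbone N or O."""
    for res in residues:
        heavy = [a for a in res.atoms if a.is_heavy]
        for atom in res.atoms:
            if atom.is_heavy:
                atom.is_backbone = atom.atom_name in BACKBONE_HEAVY
        for atom in res.atoms:
            if not atom.is_hydrogen or not heavy:
                continue
            d = [float(np.linalg.norm(atom.coords - h.coords)) for h in heavy]
            j = int(np.argmin(d))
            atom.is_backbone = (
                d[j] <= 1.25
                and heavy[j].atom_name in BACKBONE_HEAVY
                and heavy[j].element in ("N", "O")
            )


def _read_cryst1(path: Path) -> np.ndarray | None:
    with open(path) as fh:
        for line in fh:
            if line.startswith("CRYST1"):
                try:
                    a, b, c = (float(line[6:15]), float(line[15:24]), float(line[24:33]))
                    alpha, beta, gamma = (
                        float(line[33:40]), float(line[40:47]), float(line[47:54]),
                    )
                except ValueError:
                    return None
                if a * b * c == 0:
                    return None
                if not all(abs(x - 90.0) < 1e-3 for x in (alpha, beta, gamma)):
                    raise FormatError("only orthorhombic (90/90/90) boxes are supported")
                return np.array([a, b, c])
            if line.startswith(("ATOM", "HETATM", "MODEL")):
                break
    return None


def read_structure(path: str | Path, dialect: str = "pdb") -> list[StructureModel]:
    """Read a (possibly multi-model) PDB file into StructureModel objects.

    Elements come from PDB columns 77-78 when present, otherwise inferred from
    the atom name. Residues keep file order; insertion-coded residues stay in
    sequence. Raises FormatError on unparseable input and EmptyInputError when
    no atoms are present.
    """
    if dialect != "pdb":
        raise ValueError(f"unsupported dialect {dialect!r}")
    path = Path(path)
    parser = PDBParser(QUIET=True)
    try:
        bio = parser.get_structure("s", str(path))
    except Exception as exc:  # Bio.PDB raises a mix of exception types
        raise FormatError(f"cannot parse {path} as PDB: {exc}") from exc
    box = _read_cryst1(path)

    models: list[StructureModel] = []
    for bm in bio:
        chains: dict[str, list[ResidueRecord]] = {}
        for bchain in bm:
            residues: list[ResidueRecord] = []
            for bres in bchain:
                hetflag, resseq, icode = bres.id
                atoms = []
                for batom in bres:
                    element = (batom.element or "").strip()
                    if not element:
                        element = _infer_element(batom.get_name())
                    atoms.append(
                        AtomRecord(batom.get_name(), element, np.asarray(batom.coord, float))
                    )
                if atoms:
                    residues.append(
                        ResidueRecord(
                            chain_id=bchain.id,
                            resseq=int(resseq),
                            resname=bres.get_resname().strip(),
                            icode=icode.strip(),
                            atoms=atoms,
                        )
                    )
            if residues:
                _flag_backbone(residues)
                chains[bchain.id] = residues
        if chains:
            models.append(StructureModel(model_id=int(bm.id), chains=chains, box=box))
    if not models:
        raise EmptyInputError(f"{path}: no ATOM records")
    return models


def write_structure(models: StructureModel | Sequence[StructureModel], path: str | Path) -> None:
    """Write one or more models as a (multi-model) PDB file."""
    if isinstance(models, StructureModel):
        models = [models]
    if not models:
        raise EmptyInputError("nothing to write")
    path = Path(path)
    lines: list[str] = []
    if models[0].box is not None:
        a, b, c = models[0].box
        lines.append(
            f"CRYST1{a:9.3f}{b:9.3f}{c:9.3f}{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1"
        )
    multi = len(models) > 1
    for k, model in enumerate(models, start=1):
        if multi:
            lines.append(f"MODEL     {k:4d}")
        serial = 1
        for cid, residues in model.chains.items():
            for res in residues:
                for atom in res.atoms:
                    name = atom.atom_name
                    # standard PDB alignment: 1-letter elements start in col 14
                    padded = f" {name:<3s}" if len(name) < 4 and len(atom.element) == 1 else f"{name:<4s}"
                    x, y, z = atom.coords
                    lines.append(
                        f"ATOM  {serial:5d} {padded}{'':1s}{res.resname:>3s} {cid:1s}"
                        f"{res.resseq:4d}{res.icode:1s}   "
                        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
                        f"{atom.element:>2s}"
                    )
                    serial += 1
            lines.append(f"TER   {serial:5d}      {residues[-1].resname:>3s} {cid:1s}{residues[-1].resseq:4d}")
            serial += 1
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# pAE matrices
# ---------------------------------------------------------------------------

def _chain_vector(n: int, chain_lengths: Sequence[int] | None,
                  chain_labels: Sequence[str] | None) -> np.ndarray:
    if chain_lengths is None:
        return np.array(["A"] * n)
    if sum(chain_lengths) != n:
        raise ValueError(
            f"chain lengths {list(chain_lengths)} sum to {sum(chain_lengths)}, matrix is {n}x{n}"
        )
    if chain_labels is None:
        chain_labels = [chr(ord("A") + i) for i in range(len(chain_lengths))]
    if len(chain_labels) != len(chain_lengths):
        raise ValueError("chain_labels and chain_lengths must have equal length")
    out: list[str] = []
    for lab, ln in zip(chain_labels, chain_lengths):
        out.extend([lab] * ln)
    return np.array(out)


def read_pae(path: str | Path, chain_lengths: Sequence[int] | None = None,
             chain_labels: Sequence[str] | None = None) -> PAEMatrix:
    """Read a pAE matrix from ColabFold-style JSON or a delimited text matrix.

    JSON files may carry the matrix under ``predicted_aligned_error`` or
    ``pae`` (optionally inside a one-element list, as ColabFold writes it) and
    may carry ``plddt``. Chain assignment comes from the file when present,
    otherwise from ``chain_lengths``/``chain_labels``.
    """
    path = Path(path)
    text = path.read_text()
    stripped = text.lstrip()
    plddt = None
    if stripped.startswith(("{", "[")):
        payload = json.loads(text)
        if isinstance(payload, list):
            if not payload:
                raise FormatError(f"{path}: empty JSON array")
            payload = payload[0]
        if not isinstance(payload, dict):
            raise FormatError(f"{path}: JSON must contain an object")
        arr = payload.get("predicted_aligned_error", payload.get("pae"))
        if arr is None:
            raise FormatError(f"{path}: no 'predicted_aligned_error' or 'pae' key")
        values = np.asarray(arr, dtype=float)
        if "plddt" in payload:
            plddt = np.asarray(payload["plddt"], dtype=float)
        if chain_lengths is None and "chain_lengths" in payload:
            chain_lengths = payload["chain_lengths"]
        if chain_labels is None and "chain_labels" in payload:
            chain_labels = payload["chain_labels"]
    else:
        try:
            values = np.loadtxt(StringIO(text.replace(",", " ")), dtype=float, ndmin=2)
        except ValueError as exc:
            raise FormatError(f"{path}: cannot parse numeric matrix: {exc}") from exc
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise FormatError(f"{path}: pAE array is not square (shape {values.shape})")
    chain_of = _chain_vector(values.shape[0], chain_lengths, chain_labels)
    return PAEMatrix(values=values, chain_of=chain_of, plddt=plddt)


def write_pae_json(pae: PAEMatrix, path: str | Path) -> None:
    """Write a PAEMatrix as ColabFold-style JSON (with chain metadata)."""
    labels, lengths = [], []
    for lab in pae.chain_of:
        if not labels or labels[-1] != str(lab):
            labels.append(str(lab))
            lengths.append(0)
        lengths[-1] += 1
    payload = {
        "predicted_aligned_error": np.round(pae.values, 4).tolist(),
        "chain_labels": labels,
        "chain_lengths": lengths,
    }
    if pae.plddt is not None:
        payload["plddt"] = np.round(pae.plddt, 2).tolist()
    Path(path).write_text(json.dumps(payload))


# ---------------------------------------------------------------------------
# Sequences and posterior tables
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[SequenceRecord]:
    records = [SequenceRecord(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise EmptyInputError(f"{path}: no FASTA records")
    return records


def write_fasta(records: Sequence[SequenceRecord], path: str | Path) -> None:
    SeqIO.write(
        [_BioSeqRecord(_BioSeq(r.seq), id=r.id, description="") for r in records],
        str(path), "fasta",
    )


def read_posterior_table(path: str | Path, alphabet: str = AA_ALPHABET) -> PosteriorTable:
    """Read a per-site posterior table: one row per site, 20 probability
    columns in the declared amino-acid order (optional leading site column and
    header line are detected). Rows whose sum is within 1e-3 of 1 are
    renormalised; larger deviations raise."""
    import pandas as pd

    df = pd.read_csv(path, sep=None, engine="python", header=None, comment="#")
    # header row of letters?
    if df.iloc[0].astype(str).str.fullmatch(r"[A-Za-z_]+").all():
        df = df.iloc[1:].reset_index(drop=True)
    df = df.apply(pd.to_numeric)
    site_index = None
    if df.shape[1] == len(alphabet) + 1:
        site_index = df.iloc[:, 0].astype(int).to_numpy()
        df = df.iloc[:, 1:]
    if df.shape[1] != len(alphabet):
        raise FormatError(
            f"{path}: expected {len(alphabet)} probability columns, got {df.shape[1]}"
        )
    return PosteriorTable(probs=df.to_numpy(float), alphabet=alphabet, site_index=site_index)


def write_posterior_table(table: PosteriorTable, path: str | Path) -> None:
    import pandas as pd

    df = pd.DataFrame(table.probs, columns=list(table.alphabet))
    df.insert(0, "site", table.site_index)
    df.to_csv(path, sep="\t", index=False)
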