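"""Sequence-level rules: C-terminal PDZ-binding motif classes, conserved-motif
search, domain-boundary padding, and maximum-posterior ancestral sequences.

PDZ ligands are classified by their C-terminal triplet (positions -2, -1, 0,
the last residue being 0):

  type I    S/T - X - hydrophobic
  type II   hydrophobic - X - hydrophobic
  type III  D/E - X - hydrophobic

with the hydrophobic set {V, I, L, F, W, Y, M}. X is unconstrained. The three
classes are mutually exclusive because they differ at position -2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import PosteriorTable, SequenceRecord

__all__ = [
    "HYDROPHOBIC", "MotifCall", "DomainWindow", "AncestralMAP",
    "classify_cterm_motif", "find_motif", "extend_and_extract", "map_ancestral",
]

HYDROPHOBIC = frozenset("VILFWYM")


@dataclass
class MotifCall:
    seq_id: str
    cterm: str                      # last three residues
    motif_type: str                 # "I" | "II" | "III" | "none"

    @property
    def is_consensus(self) -> bool:
        return self.motif_type != "none"


@dataclass
class DomainWindow:
    seq_id: str
    core_start: int
    core_end: int
    ext_start: int
    ext_end: int


@dataclass
class AncestralMAP:
    map_seq: str
    confident_mask: np.ndarray
    threshold: float
    mean_posterior: float


def classify_cterm_motif(seq: SequenceRecord) -> MotifCall:
    """Type the C-terminal PDZ-binding motif from the last three residues.

    Position 0 (the last residue) must be hydrophobic for any class; the -2
    residue then decides: S/T -> type I, hydrophobic -> type II, D/E -> type
    III, anything else -> none.
    """
    if len(seq) < 3:
        raise ValueError(f"{seq.id}: need at least 3 residues to type a C-terminal motif")
    cterm = seq.seq[-3:]
    p0, pm2 = cterm[2], cterm[0]
    if p0 not in HYDROPHOBIC:
        motif = "none"
    elif pm2 in "ST":
        motif = "I"
    elif pm2 in HYDROPHOBIC:
        motif = "II"
    elif pm2 in "DE":
        motif = "III"
    else:
        motif = "none"
    return MotifCall(seq_id=seq.id, cterm=cterm, motif_type=motif)


def find_motif(seq: SequenceRecord, pattern: str = "GLGF") -> list[int]:
    """1-based start offsets of all (possibly overlapping) exact occurrences
    of ``pattern`` — e.g. the conserved carboxylate-binding GLGF tetrapeptide."""
    if not pattern:
        raise ValueError("pattern must be non-empty")
    pattern = pattern.upper()
    hits, start = [], 0
    while True:
        i = seq.seq.find(pattern, start)
        if i < 0:
            return hits
        hits.append(i + 1)
        start = i + 1


def extend_and_extract(seq: SequenceRecord, core_start: int, core_end: int,
                       pad: int = 10) -> tuple[DomainWindow, str]:
    """Pad predicted domain boundaries by ``pad`` residues on each side,
    clamped to the sequence, and return the extracted subsequence.

    ``core_start``/``core_end`` are 1-based inclusive.
    """
    n = len(seq)
    if not (1 <= core_start <= core_end <= n):
        raise ValueError(
            f"{seq.id}: invalid core ({core_start}, {core_end}) for length {n}"
        )
    ext_start = max(1, core_start - pad)
    ext_end = min(n, core_end + pad)
    window = DomainWindow(seq.id, core_start, core_end, ext_start, ext_end)
    return window, seq.seq[ext_start - 1:ext_end]


def map_ancestral(table: PosteriorTable, threshold: float = 0.5) -> AncestralMAP:
    """Maximum-posterior ancestral sequence with a per-site confidence mask.

    Each site takes the amino acid with the highest posterior probability
    (ties broken alphabetically); the site is flagged confident when that
    maximum is at least ``threshold``.
    """
    letters = np.array(list(table.alphabet))
    order = np.argsort(letters)  # alphabetical scan order => first max is the tie-break
    probs = table.probs[:, order]
    best = np.argmax(probs, axis=1)
    maxima = probs[np.arange(probs.shape[0]), best]
    seq = "".join(letters[order][best])
    mask = maxima >= threshold
    return AncestralMAP(
        map_seq=seq,
        confident_mask=mask,
        threshold=threshold,
        mean_posterior=float(np.mean(maxima)),
    )
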