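"""Local interaction score (LIS) from predicted-aligned-error matrices.

The LIS of a two-chain complex looks at the interchain block of the pAE
matrix, keeps values below a cutoff (12 Å by default), rescales them linearly
so pAE 0 -> 1 and pAE = cutoff -> 0, and averages. A higher LIS indicates a
more confident interface prediction. Because the source description reads
"averaged those values", the default denominator is the below-cutoff subset;
an alternative convention that averages over all interchain elements
(above-cutoff elements contributing 0) is also provided, which makes the
score monotone in every matrix element.

The mean of all interchain pAE values is reported alongside as
``pae_interaction``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .io import EmptyInputError, PAEMatrix

__all__ = ["InteractionScores", "SeedAggregate", "interchain_elements",
           "lis_score", "aggregate_seeds"]

Denominator = Literal["below_cutoff", "all_interchain"]


@dataclass
class InteractionScores:
    """LIS and companion statistics for one chain pair of one prediction."""

    lis: float
    pae_interaction: float
    n_interchain: int
    n_below_cutoff: int
    cutoff: float = 12.0
    denominator: Denominator = "below_cutoff"

    def __post_init__(self) -> None:
        if not 0.0 <= self.lis <= 1.0:
            raise ValueError(f"lis {self.lis} outside [0, 1]")
        if self.n_below_cutoff > self.n_interchain:
            raise ValueError("n_below_cutoff exceeds n_interchain")


@dataclass
class SeedAggregate:
    """Mean ± sample standard deviation of LIS over prediction seeds."""

    mean_lis: float
    sd_lis: float
    n_seeds: int


def interchain_elements(pae: PAEMatrix, chain_a: str, chain_b: str) -> np.ndarray:
    """All pAE values between two chains: both off-diagonal blocks, since the
    pAE matrix is not symmetric."""
    if chain_a == chain_b:
        raise ValueError("chain_a and chain_b must differ for interchain scoring")
    labels = pae.chain_of.astype(str)
    for lab in (chain_a, chain_b):
        if lab not in labels:
            raise KeyError(f"chain {lab!r} not in pAE chain assignment "
                           f"(have {sorted(set(labels))})")
    a = labels == chain_a
    b = labels == chain_b
    block_ab = pae.values[np.ix_(a, b)]
    block_ba = pae.values[np.ix_(b, a)]
    return np.concatenate([block_ab.ravel(), block_ba.ravel()])


def lis_score(pae: PAEMatrix, chain_a: str, chain_b: str, cutoff: float = 12.0,
              denominator: Denominator = "below_cutoff") -> InteractionScores:
    """Compute the LIS for one chain pair.

    Elements strictly below ``cutoff`` are rescaled as (cutoff - x)/cutoff.
    With ``denominator='below_cutoff'`` the score averages only those rescaled
    values (0 if none fall below the cutoff); with ``'all_interchain'`` the
    sum of rescaled values is divided by the count of all interchain elements.
    """
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    elements = interchain_elements(pae, chain_a, chain_b)
    below = elements[elements < cutoff]
    scaled_sum = float(np.sum((cutoff - below) / cutoff))
    if denominator == "below_cutoff":
        lis = scaled_sum / below.size if below.size else 0.0
    elif denominator == "all_interchain":
        lis = scaled_sum / elements.size if elements.size else 0.0
    else:
        raise ValueError(f"unknown denominator convention {denominator!r}")
    return InteractionScores(
        lis=float(lis),
        pae_interaction=float(np.mean(elements)) if elements.size else 0.0,
        n_interchain=int(elements.size),
        n_below_cutoff=int(below.size),
        cutoff=float(cutoff),
        denominator=denominator,
    )


def aggregate_seeds(scores: Sequence[InteractionScores | float]) -> SeedAggregate:
    """Mean and sample standard deviation (n-1 denominator; 0 for a single
    seed) of LIS values across prediction seeds."""
    if len(scores) == 0:
        raise EmptyInputError("no scores to aggregate")
    values = np.array([s.lis if isinstance(s, InteractionScores) else float(s)
                       for s in scores])
    # exact zero for constant input (np.std returns O(eps) noise there)
    if values.size == 1 or np.ptp(values) == 0.0:
        sd = 0.0
    else:
        sd = float(np.std(values, ddof=1))
    return SeedAggregate(mean_lis=float(np.mean(values)), sd_lis=sd, n_seeds=values.size)
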