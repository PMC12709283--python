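#!/usr/bin/env python
"""Generate the synthetic datasets the downstream analyses consume.

Writes, under results/data/:
  pae_seed*.json      — ten two-chain pAE matrices (noisy interface, one per
                        prediction seed), PDZ-sized chain A (80 aa) + 10-aa
                        ligand chain B
  complex_*.pdb       — four toy PDZ-ligand complexes, each with hydrogen
                        bonds planted at ligand positions {0, -2} plus one
                        complex-specific extra position
  waters_lattice.pdb / waters_gas.pdb — water-oxygen configurations (ice-like
                        network vs ideal gas at equal density), 3 frames each
  embeddings.tsv / embeddings.labels.tsv — 4 Gaussian groups x 12 proteins
  posterior_node.tsv  — per-site amino-acid posteriors for a 10-residue target
"""

import argparse
from pathlib import Path

import pandas as pd

from pdzkit import io, synth

EXTRAS = [-1, -3, -4, -5]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results/data"))
    args = ap.parse_args()
    out = args.outdir
    out.mkdir(parents=True, exist_ok=True)

    for s in range(10):
        pae = synth.gen_pae(80, 10, ("noisy", 6.0, 0.5), seed=args.seed + s)
        io.write_pae_json(pae, out / f"pae_seed{s}.json")

    for j, extra in enumerate(EXTRAS):
        model = synth.gen_toy_complex(ligand_seq="YKQTSV",
                                      planted_positions={0, -2, extra},
                                      seed=args.seed + j)
        io.write_structure(model, out / f"complex_{j}.pdb")

    io.write_structure(synth.gen_waters("tetra_lattice", n=216, jitter=0.1,
                                        seed=args.seed, n_frames=3),
                       out / "waters_lattice.pdb")
    io.write_structure(synth.gen_waters("ideal_gas", n=216, seed=args.seed,
                                        n_frames=3),
                       out / "waters_gas.pdb")

    X, ids, labels = synth.gen_embeddings(k_groups=4, n_per_group=12, dims=64,
                                          separation=5.0, seed=args.seed)
    pd.DataFrame(X, index=ids).to_csv(out / "embeddings.tsv", sep="\t")
    labels.to_csv(out / "embeddings.labels.tsv", sep="\t")

    io.write_posterior_table(
        synth.gen_posterior_table("DTKNYKQTSV", confidence=0.8, seed=args.seed),
        out / "posterior_node.tsv")

    print(f"simulated inputs written to {out}/ "
          f"(10 pAE files, {len(EXTRAS)} complexes, 2 water trajectories, "
          f"1 embedding matrix, 1 posterior table)")


if __name__ == "__main__":
    main()
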