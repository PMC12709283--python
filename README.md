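# pdzkit

Structural-interaction statistics for PDZ–ligand complexes: confidence
scoring of predicted interfaces, hydrogen-bond fingerprinting by ligand
position, hydration-water tetrahedrality profiling, and the sequence rules
(binding-motif classes, domain padding, ancestral maximum-posterior
extraction) used when tracing how a peptide-binding domain's interaction
machinery evolved.

## Who this is for

PDZ domains (~80–100 aa modules of PSD-95/Dlg/ZO-1 scaffolds) bind the
C-terminal tails of their ligands. Comparing how orthologous PDZ domains from
distantly related organisms engage the same ligand family requires a stack of
small, precisely defined computations downstream of structure prediction and
molecular dynamics. `pdzkit` implements that stack as a tested library plus
numbered analysis drivers, with a synthetic-data module that emulates the
upstream outputs (predicted-aligned-error matrices, protonated complexes,
solvated frames, embedding matrices) so every stage is verifiable end to end.

## The statistics at the core

**LIS (local interaction score).** For a two-chain complex with pAE matrix
`E`, take the interchain elements `x` (both off-diagonal blocks — pAE is
asymmetric), keep `x < 12` Å, rescale each to `(12 − x)/12` so pAE 0 → 1 and
pAE 12 → 0, and average:

    LIS = mean{ (12 − x)/12 : x interchain, x < 12 }   (0 if the set is empty)

Higher LIS = more confident interface. An alternative denominator (all
interchain elements, above-cutoff entries contributing 0) is provided as
`denominator="all_interchain"`; it is monotone in every matrix element. The
mean over *all* interchain elements is reported alongside as the pAE
interaction score. Per-seed scores aggregate as mean ± sample sd.

**Hydrogen-bond fingerprints.** A bond is a donor–H–acceptor triple with
heavy-atom distance ≤ 3.7 Å and D–H–A angle ≥ 120°; donors are N/O/S with an
attached hydrogen, acceptors N/O. Bonds are intermolecular only, classified
`bb-bb`/`bb-sc`/`sc-bb`/`sc-sc` by backbone membership of the two heavy
atoms, and indexed by ligand position (C-terminal residue = 0, then −1, −2,
…). A position is *conserved* across complexes when every complex has ≥ 1
bond there.

**Water tetrahedrality.** Hydration waters are oxygens within 4.25 Å of a
probe heavy atom. For each such oxygen, the angles to every pair of
neighbouring water oxygens (within 3.4 Å, drawn from all waters) form the
triplet (three-body-angle) distribution; the *tetrahedral water fraction* is
its integral over [100°, 120°) — high around small hydrophobic moieties,
low around hydrophilic ones. Fractions pool over frames within a replica and
report mean ± sd across replicas.

**Sequence rules.** C-terminal motif classes on the last three residues
(position −2 vs 0): type I `S/T-X-Φ`, type II `Φ-X-Φ`, type III `D/E-X-Φ`,
with Φ ∈ {V,I,L,F,W,Y,M}; GLGF-motif search; ±10-residue domain-boundary
padding with clamping; per-site maximum-posterior ancestral sequences with a
0.5 confidence threshold.

**Embedding statistics.** Centred PCA of per-protein embedding vectors; per
component one-way ANOVA across PDZ groups, Tukey HSD only where ANOVA
p < 0.05, and Welch's two-tailed t between single- and multi-celled labels.

## Worked example

```python
import numpy as np
from pdzkit import synth, lis, hbonds, tetra

# interface confidence: uniform interchain pAE of 6 Å sits mid-scale
pae = synth.gen_pae(25, 10, ("constant", 6.0))
print(lis.lis_score(pae, "A", "B").lis)          # 0.5

# hydrogen bonds planted at ligand positions 0 and -2 are found, and only those
model = synth.gen_toy_complex(planted_positions={0, -2}, seed=1)
print(sorted(b.ligand_position for b in hbonds.detect_hbonds(model, "A", "B")))
# [-2, 0]

# an ice-like oxygen network is maximally tetrahedral
frame = synth.gen_waters("tetra_lattice", n=216, jitter=0.0, seed=0)[0]
n = tetra.water_oxygen_coords(frame).shape[0]
shell = tetra.HydrationShell(0, np.arange(n))
print(tetra.fraction_in_window(tetra.triplet_angles(frame, shell)))   # 1.0
```

The numbers printed are exact consequences of the definitions: pAE 6 Å maps
to (12−6)/12 = 0.5; the toy complex plants donor–H–acceptor geometries at
2.9 Å/180° only at the requested positions; every triplet angle of a perfect
tetrahedral network is 109.47°, inside [100°, 120°).

The numbered drivers under `analysis/` run the same stages over a simulated
study (generate inputs → LIS over ten prediction seeds → fingerprints and
conserved positions → lattice-vs-gas tetrahedrality → motif/ASR rules →
embedding statistics), each writing a table under `results/`:

```bash
python analysis/01_simulate_inputs.py --seed 1
python analysis/02_lis_scoring.py
...
```

A `pdzkit` console command exposes the same operations on files
(`pdzkit lis`, `pdzkit hbonds`, `pdzkit tetra`, `pdzkit motif`,
`pdzkit asr-map`, `pdzkit embed-stats`, `pdzkit simulate`, …); see
`pdzkit --help`.

## Layout

    src/pdzkit/      library: io, lis, hbonds, tetra, motifs, embed, synth, cli
    analysis/        numbered narrative drivers writing results/*.tsv
    tests/           pytest suite with brute-force oracles and property tests
    scripts/         acceptance.py (see above)
    docs/methods.md  models, conventions, numerical choices, limitations
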