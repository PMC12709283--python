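# Methods

This note records the models implemented in `pdzkit`, the conventions and
defaults chosen where the underlying definitions leave room, what the
synthetic generators do and do not emulate, and known limitations.

## Interface confidence: LIS and pAE interaction

A predicted-aligned-error (pAE) matrix gives, for every ordered residue pair
(i, j), the expected positional error (Å) of residue j when the prediction is
aligned on residue i; it is not symmetric. For a two-chain complex the
interchain elements — both off-diagonal blocks, pooled without
symmetrisation — gauge interface confidence.

The local interaction score keeps interchain elements strictly below a
cutoff (default 12 Å), maps each linearly to `(cutoff − x)/cutoff` (so 0 Å →
1 and the cutoff → 0), and averages. Two denominator conventions are
implemented because the verbal definition ("average those values") is
ambiguous:

- `below_cutoff` (default): average only the rescaled below-cutoff values;
  0 when none fall below the cutoff. Literal reading. Note this score is not
  monotone in the matrix: pushing a mediocre element past the cutoff removes
  it from the denominator and can raise the score. It equals 1 exactly when
  the below-cutoff subset is non-empty and all-zero.
- `all_interchain`: divide the same sum by the count of all interchain
  elements, i.e. above-cutoff elements contribute 0. Monotone non-increasing
  in every element; equals 1 iff every interchain element is 0.

The `pae_interaction` field is the plain mean of all interchain elements.
This is a documented assumption — the quantity circulates under that name
with no single published formula — and nothing in the test suite asserts it
against external values.

Aggregation across prediction seeds is mean ± sample standard deviation
(n − 1 denominator; exactly 0 for a single seed or for constant input).

## Hydrogen-bond fingerprints

Geometric criterion: heavy-atom donor–acceptor distance ≤ 3.7 Å and
donor–hydrogen–acceptor angle ≥ 120° (180° = linear). Donors are N, O or S
heavy atoms with at least one hydrogen within 1.25 Å (proximity parenting;
connectivity records are absent from predicted structures); acceptors are N
or O. Sulfur is accepted as donor but not acceptor — a conservative superset
covering Cys/Met chemistry that cannot add carboxylate-pocket bonds. Only
intermolecular bonds between the two designated chains are reported, in both
donor directions.

Structures without explicit hydrogens raise a protonation error rather than
silently returning nothing; a helper that attaches idealised backbone amide
hydrogens along a fixed direction exists for synthetic fixtures only.

Bond classes: the donor-side and acceptor-side heavy atoms are each labelled
backbone (`bb`) or side-chain (`sc`). The backbone set is {N, CA, C, O, OXT}
plus hydrogens attached to the backbone N — so C-terminal carboxylate
oxygens count as backbone, and carboxylate bonds at ligand position 0
classify as `bb`. Ligand positions count back from the C-terminus (last
residue 0, then −1, −2, …), the numbering in which the −2 residue
discriminates the motif classes. Reported residue numbers are the input
file's author numbering; no renumbering is imposed.

Detection uses a k-d tree over acceptor coordinates; the test suite checks
exact agreement with an exhaustive all-triples enumeration and invariance
under random rigid motions.

## Water tetrahedrality

Hydration waters are water-residue oxygens (HOH/WAT/SOL/TIP*/SPC; virtual
sites of 4- and 5-site models excluded) within `r_hyd` = 4.25 Å of any
designated probe heavy atom. For each hydration oxygen, every unordered pair
of neighbouring water oxygens within `r_nb` of it defines a triplet angle at
the central oxygen; neighbours are drawn from all waters in the frame so
shell-boundary oxygens get complete neighbourhoods. The tetrahedral water
fraction is the share of triplet angles in [100°, 120°), the band around the
ideal tetrahedral angle arccos(−1/3) ≈ 109.47°; it is computed as a count
ratio, which equals the integral of the normalised histogram when the window
lies on bin edges (default 1° bins aligned at 0°, so it does).

Choices worth stating:

- `r_nb` defaults to 3.4 Å, the first-hydration-shell O–O distance
  convention of the triplet-distribution literature; it is a parameter, not
  a derived quantity.
- When the site of interest is an amide hydrogen, the default probe is its
  parent heavy atom (`probe_mode="parent_heavy"`), reconciling
  "tetrahedrality at a hydrogen-bond donor" with a shell defined relative to
  heavy atoms; `residue_heavy` and `hydrogen` modes are available.
- Frames within a replica pool their triplet counts before the fraction is
  taken (equivalent to triplet-count-weighted averaging of per-frame
  fractions); the mean and sd reported across replicas use the sample sd.
- Periodic boundaries: orthorhombic boxes only (CRYST1 with 90° angles),
  applied through minimum-image distances in both shell selection and
  neighbour search. Triclinic boxes are not supported.

Neighbour searches use a k-d tree; tests pin exact agreement with a
brute-force distance-matrix oracle up to n = 2000 oxygens.

## Sequence rules

- Motif classes are decided by positions 0 and −2 of the C-terminal triplet
  only; the −1 "X" is unconstrained (it may itself be hydrophobic or
  charged). Position 0 must be hydrophobic ({V,I,L,F,W,Y,M}) for any class;
  −2 ∈ {S,T} → I, hydrophobic → II, {D,E} → III, else none. The three
  classes are mutually exclusive by construction; the suite verifies the
  partition by exhaustive enumeration of all 8000 triplets against an
  independent rule table.
- Domain windows extend annotated cores by 10 residues on each side, clamped
  to the sequence.
- Ancestral maximum-posterior extraction takes the per-site argmax with an
  alphabetical tie-break (ties are measure-zero in real tables; the rule
  buys determinism) and flags sites whose maximum is ≥ the threshold
  (default 0.5, inclusive).

## Embedding statistics

PCA is centred and unscaled by default (a `scale` flag standardises
dimensions first); component signs are fixed by making each component's
largest-magnitude loading positive. Rank-deficient inputs truncate with a
warning. Per component: one-way ANOVA across PDZ groups (groups with < 2
members are dropped; < 2 usable groups flags the component as skipped),
Tukey HSD pairwise p-values computed only when the ANOVA p < 0.05 (the
dashed-entry reporting convention), and Welch's two-tailed t-test between
single- and multi-celled labels. With zero within-group variance the ANOVA
p is defined as 1 for identical group means and 0 otherwise.

## Synthetic generators: what they emulate, what they do not

All generators are deterministic in (parameters, seed).

- **Waters.** `tetra_lattice` places oxygens on a diamond-cubic (ice-like)
  network at a chosen number density (default 0.0312 Å⁻³, near liquid
  water's) with isotropic Gaussian jitter; at zero jitter every
  nearest-neighbour triplet angle is exactly 109.47°, so the downstream
  fraction is exactly 1. `ideal_gas` draws uniform positions with a 2.4 Å
  hard core at the same density — no angular order, fraction near the
  geometric baseline (~0.17). A probe carbon sits at the configuration
  centre so hydration-shell selection is exercised. These are *point
  configurations with controllable order*, not physical water: no
  hydrogens, no H-bond network dynamics, no temperature. Passing tests show
  the geometry/counting pipeline is exact and discriminates planted order,
  not that any force field is reproduced.
- **pAE matrices.** Intrachain blocks flat at 2 Å, interchain blocks
  constant, two-level or Gaussian, clipped to [0, 31.75]. No attempt to
  mimic the spatial error correlations of real predictions.
- **Toy complexes.** Two extended strands; the pocket strand carries a
  chosen motif (default GLGF, padded with Ala) and amide hydrogens pointing
  at the ligand; planted positions get the ligand carbonyl oxygen placed
  2.9 Å from the facing pocket nitrogen on the N–H axis (θ = 180°), inside
  the detection cutoffs with margin, while all other ligand polar atoms stay
  ≥ 8 Å away. Jitter (0.02 Å) is kept an order of magnitude below the
  margins so detection never sits on a decision boundary. The geometry is a
  planted-truth fixture, not a fold.
- **Embeddings.** Isotropic Gaussian clusters whose means are spaced by a
  chosen multiple of the noise sd along one random direction; group 0 is
  labelled single-celled. Real embedding geometry (anisotropy, manifold
  structure) is not emulated.
- **Posterior tables.** The target residue gets exactly the requested
  confidence, the remainder spread uniformly — exact placement keeps
  threshold-boundary behaviour (confidence 0.5 at threshold 0.5) testable.

## Problem sizes and numerical notes

The test suite and the acceptance script run on deliberately small problems:
water configurations of 150–2000 oxygens (oracle-equivalence checks sample
46 configurations at 200–700 plus four at 1500–2000), 100 toy complexes,
100-replicate power/type-I studies at 4 groups × 12 proteins × 64
dimensions, ten-seed LIS aggregates on 50-residue complexes. These sizes
make the brute-force oracles exact and the whole suite rerunnable in a few
minutes while exercising every code path; the statistics themselves are
size-agnostic.

Angles are computed via clipped arccos of normalised dot products; fractions
use half-open windows [lo, hi) so bin edges are counted once; PDB coordinates
round-trip at the format's 10⁻³ Å precision; posterior rows renormalise when
|sum − 1| ≤ 10⁻³ and are rejected beyond that.

## Limitations

- No mmCIF input; PDB only (multi-model allowed). Binary trajectory formats
  (DCD/XTC) must be converted upstream.
- H-bond detection requires explicit hydrogens and does not model
  water-mediated bridges or bond energetics.
- Only orthorhombic periodic boxes are handled.
- The embedding stage consumes pre-computed matrices; language-model
  inference is out of scope, as are structure prediction and MD themselves —
  published headline values that depend on those upstream engines (specific
  interface scores of real complexes, per-site tetrahedrality of real PDZ
  pockets, per-component p-values of real embeddings) are therefore not
  asserted anywhere; the suite validates the computations on inputs with
  known planted truth instead.
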