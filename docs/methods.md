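# Methods

`ctdkit` re-implements, as a tested library, the bespoke computational
analyses used to characterize phase-separating heptad-repeat
low-complexity domains — above all the carboxy-terminal domain (CTD) of
RNA polymerase II, whose consensus repeat is Y₁S₂P₃T₄S₅P₆S₇.  The
analyses fall into three groups: residue-contact statistics with a
randomized-sequence background, geometric analysis and RMSD clustering of
stable residue pairs, and conformer-ensemble observables with
maximum-entropy reweighting.  Because the original microsecond all-atom
trajectories and the NMR restraint lists are not available in
machine-readable form, every operation is exercised on synthetic
multi-copy systems with *planted* ground truth; the headline literature
numbers (e.g. a 14% Pro–Tyr contact fraction, 1.8×/0.7× enrichments,
70%/52% cluster occupancies) are context for the method, not quantities
this package can reproduce at desk scale.

## Contact statistics

A *contact* between two residues exists in a frame when any interatomic
distance between them is at or below a cutoff (default 3.5 Å, the value
used for all-atom condensate trajectories; the comparison is inclusive,
pinned by boundary fixtures).  When the frame carries an orthorhombic
box, all distances use the minimum-image convention, so contacts across
periodic images count.  Frequencies are computed over an analysis window
sampled on a stride grid anchored at the window start (defaults: the last
300 ns at 1 ns).  Intramolecular statistics exclude sequence neighbours
|i−j| < 2 by default, since those contacts are forced by connectivity;
the exclusion is configurable down to 0 because the original analysis
does not state one.  The implementation reduces the all-atom distance
matrix to residue pairs with two `minimum.reduceat` passes and is checked
against an exhaustive all-pair, 27-image brute force on randomized
systems (that oracle presumes coordinates wrapped into the primary box;
the library path itself is wrap-agnostic).

*Enrichment* of a contact type (a, b) is the observed fraction of
contact events of that type divided by the expected fraction under a
randomized sequence background, 2·f_a·f_b for a ≠ b and f_a² otherwise,
where f are residue-type frequencies.  Contact events are pair×frame
occurrences — a pair in contact for many frames contributes
proportionally; unique-pair counting is available behind a flag.  The
analytic background is pinned by an explicit label-permutation test
(`shuffle_background`): labels are permuted over residues, events
re-typed, and mean fractions reported with standard errors.  The
permutation draws labels *without replacement*, so its expectation
differs from the composition product by O(1/N) in the residue count N;
the two agree within Monte-Carlo error for the system sizes used here
(N ≳ 300).

The heptad-position matrix bins contact events between *canonical*
residues (identity equals the consensus at the residue's heptad position)
by position pair and normalizes by a position-frequency background
(2/49 off-diagonal, 1/49 diagonal in a pure repeat).  Canonicality is
residue-level, matching the position-resolved reading of the original
matrix; a residue-type background variant is available behind a flag.

## Stable pairs and clustering

Stable pairs are residue pairs whose contact frequency over the analysis
window strictly exceeds a threshold (10%).  For each stable pair,
snapshots are pooled at fixed spacing (10 ns) on an end-exclusive grid
([start, end), so a 0.3 µs window yields exactly 30 snapshots per pair)
into a master trajectory of two-residue configurations.  Separations are
distances between centers of geometry: for Pro the complete heavy-atom
residue, for Tyr the side-chain heavy atoms (CB, CG, CD1, CD2, CE1, CE2,
CZ, OH); a residue crossing the periodic boundary is rigidly shifted to
the image nearest its partner before extraction.

Clustering follows the greedy neighbour-count (GROMOS) scheme: the
configuration with the most neighbours within an RMSD cutoff becomes a
cluster center, the cluster is removed, and the procedure repeats; ties
go to the lowest configuration id (the reference tool leaves tie
behaviour unspecified).  RMSD is computed after optimal least-squares
superposition restricted to proper rotations, so mirror images never
collapse to zero; hydrogens are included when present ("all-atom") and a
heavy-only scope exists.  Occupancy curves report the top-cluster
population against the RMSD cutoff, with both the clustered set and the
denominator restricted to configurations separated by less than 2 nm
(the filter is applied before clustering; applying it only to the
denominator was the other defensible reading).  Clustering cost is
quadratic in configurations, so the pipeline evenly subsamples masters
beyond a configurable size (default 400) before clustering; histograms
always use the full master.

## Ensemble observables and reweighting

An ensemble is a set of independent conformers with reference weights
w⁰.  Backbone turns in a 4-residue window i..i+3 are counted when the
O(i)–N(i+3) distance is strictly below 5 Å.  NOE upper bounds are matched
by the r⁻⁶-averaged effective distance (Σᵢ wᵢ rᵢ⁻⁶)^(−1/6) with an
inclusive 5.65 Å threshold; r⁻³ and ensemble-minimum conventions exist
for sensitivity analysis because the original matching convention is not
stated.  The hydrodynamic radius uses the Kirkwood double-sum
approximation over Cα atoms, 1/R_h = (1/N²)·Σ_{i≠j} 1/r_ij — a
documented stand-in, since the exact shape-based algorithm used in the
original workflow is not specified in reproducible detail.  Power-law
R_h(N) curves default to widely used scaling constants (folded
4.75·N^0.29, IDP 2.49·N^0.509, denatured 2.21·N^0.57 Å) and are
config-exposed.

Reweighting minimizes G(w) = ½χ²(w) + θ·S_KL(w‖w⁰) over the simplex,
with χ² = Σ_j((⟨y_j⟩_w − y_j^exp)/σ_j)² and S_KL = Σᵢ wᵢ ln(wᵢ/wᵢ⁰).
Weights are parameterized as a softmax of log-weights (positivity and
normalization exact), optimization starts at w⁰, uses L-BFGS with
analytic gradients to a 10⁻⁸ gradient tolerance and a 10⁵ iteration cap,
and anneals θ downward with warm starts because the χ² term is stiff at
small σ.  θ is the confidence parameter: the same operation serves
fragment-level refinement (θ_f = 20 in the original workflow) and global
reweighting (θ = 10, 25); staging is the pipeline's responsibility.
Chemical-shift-style observables are always inputs — predicted columns
may come from any predictor or from the synthetic generator.

## The synthetic generator

The generator is the package's ground-truth instrument, not a physical
model of CTD phase separation.  Chains are coarse pseudo-atom polymers:
a persistent self-avoiding Cα walk at 3.8 Å spacing carrying N, C, O at
ideal offsets, plus pseudo side chains (Tyr: CB, a six-membered
pseudo-ring CG–CZ and OH; Pro: CB, CG, CD; every other residue a single
CB).  Multi-copy systems are sampled by Metropolis Monte Carlo with
rigid chain translations/rotations plus pivot and crankshaft moves,
under square-well attractions between per-residue interaction sites in a
periodic box.  Temperature enters only as a scale on well depths (kT
units).  Frame times are synthetic (1 ns per sampled frame) so the
contact module's window/stride conventions apply unchanged.

Two linked design choices make the planted signal a clean ground truth:

- **The interaction site is the CB pseudo-atom** (Cα for glycine).  CB
  has identical local geometry for every residue type, so with all well
  depths zero the chain conformations are statistically independent of
  the type labels — the null model is exactly type-exchangeable.
- **Contacts in the synthetic systems are measured between CB atoms at
  the well range** (5.5 Å).  A CB–CB contact then coincides exactly with
  an occupied interaction well, so a planted Tyr–Pro well depth ε maps
  directly onto the Tyr–Pro contact enrichment.  The all-atom 3.5 Å
  default is unchanged and is what atomistic inputs should use; measuring
  the coarse model's contacts with the all-atom criterion would bias the
  background through the type-dependent pseudo-side-chain sizes
  (tyrosine's ring reaches several Å further than serine's CB), which is
  a property of the stand-in geometry, not of the statistics under test.

Reference study conditions (encoded once in `ctdkit.studies`): wild-type
chains of 10 repeats, 4 copies in a 7 nm box (≈19 mM — crowded by
design; the literature multi-copy box is 10 copies at 20 nm ≈ 2 mM,
which at desk scale would produce almost no contacts), well range 5.5 Å,
hard core 3.0 Å, 1400 Monte-Carlo sweeps of which 400 are equilibration,
and 6 independent replicas of 25 frames sampled every 40 sweeps.  The
replica count matters more than the frame count: the slow variable is
which chains happen to cluster, and pooling independent replicas is what
tames it.  Enrichment standard errors are frame-resampling SEs on the
pooled per-frame type fractions.

With those conditions the calibration and recovery properties hold: null
systems give all type-pair enrichment ratios within 3 SE of 1; planted
ε_YP ∈ {0.5, 1.0, 1.5} kT gives Y–P ratios above 1, increasing in ε and
maximal among type pairs; and an attraction planted only between
position-1 Tyr and position-6 Pro puts the heptad-matrix maximum at
(1, 6).  Because the criteria are statistical, they carry the usual
~3 SE false-alarm probability (a few percent over the dozens of z-scores
examined) — a failed run at one seed should be re-examined at another
before suspecting the code.

What the generator does *not* emulate: aromatic stacking geometry,
electrostatics and salt dependence, solvent and crowding agents,
temperature-dependent phase behaviour (LCST), cis/trans proline
isomerism, and realistic backbone dihedral statistics.  Passing tests
therefore demonstrate the *analyses* are correct and calibrated, not
that the coarse model reproduces CTD condensate physics.

## Numerical choices and degenerate inputs

- Internal unit is Å everywhere; nm appears only at configuration
  surfaces and converts exactly (×10).
- Contact cutoffs, NOE thresholds and cluster cutoffs compare
  inclusively (≤); turn detection is strictly `<` (both pinned by
  fixtures at the boundary).
- Stable-pair selection is strictly `>` the threshold ("greater than
  10%").
- Multi-model PDB is the mandatory interchange format (biotite-backed);
  frame times travel in `REMARK   6 TIME_PS` lines because PDB has no
  time record, and files without them get a 1 ns grid.  Water and ion
  records are dropped on read with a logged count.
- Chains with identical residue sequences are copies of one species,
  `copy_index` assigned in file order.
- Empty windows, off-grid spacings, zero-atom selections, unresolvable
  NOE selectors, inconsistent fixture declarations and too-small boxes
  all raise `ValidationError` rather than returning partial results;
  model inconsistencies across PDB models raise
  `StructuralInconsistencyError`.
- Report bundles contain no wall-clock timestamps, so identical
  config+seed reruns are byte-identical; the manifest echoes the full
  configuration, seeds and input checksums.

## Known limitations

- The permutation background differs from the composition product by
  O(1/N); on systems below ~100 residues the difference is resolvable at
  n_shuffles = 1000.
- The Kirkwood R_h is a lower-order approximation; absolute values
  should not be compared against shape-based estimators beyond ~10%.
- The Monte-Carlo sampler is a ground-truth generator, not an ergodic
  sampler of a physical ensemble; near-saturating well depths (≳2 kT
  with many sticky residues) drive collapse that dilutes type-specific
  enrichment, which is why the planted grid stops at 1.5 kT.
- `ContactTable.from_tsv` restores aggregate counts only; frame-resolved
  statistics (interactivity, partner counts) need the in-memory table.
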