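# ctdkit

Contact statistics, pair-geometry clustering and ensemble reweighting
for heptad-repeat low-complexity domains.

The carboxy-terminal domain (CTD) of RNA polymerase II — tandem repeats
of the consensus heptad Y₁S₂P₃T₄S₅P₆S₇ — phase-separates into
liquid-like condensates, and the interactions that drive this
(tyrosine-engaging contacts, notably Tyr–Pro) are probed computationally
with a specific battery of analyses: per-frame residue contact maps over
molecular-dynamics trajectories, contact-type enrichment against a
randomized sequence background, heptad-position interaction matrices,
RMSD clustering of stable Pro–Tyr pair configurations, and NMR-driven
conformer-ensemble refinement.  `ctdkit` implements that battery as a
reusable, tested Python library for anyone studying repeat-rich
intrinsically disordered regions in multi-chain (condensate-like)
simulations.

The core quantities:

- **Contact frequency** of residue pair (i, j): the fraction of analyzed
  frames with any interatomic distance ≤ 3.5 Å (minimum-image in a
  periodic box), over a window/stride grid (defaults: last 300 ns, 1 ns).
- **Enrichment** of contact type (a, b): observed fraction of contact
  events divided by the random-background expectation 2·f_a·f_b (f_a²
  on the diagonal), equivalently pinned by an explicit label-permutation
  test.
- **Stable pairs** (frequency > 10%) pooled into 10 ns-spaced master
  trajectories and clustered with the greedy GROMOS neighbour-count
  algorithm under all-atom RMSD cutoffs of 0.5–1 Å, with occupancies
  measured on configurations separated by < 2 nm.
- **Ensemble refinement**: maximum-entropy reweighting
  min_w ½χ²(w) + θ·S_KL(w‖w⁰), r⁻⁶-averaged NOE upper-bound matching at
  5.65 Å, O(i)–N(i+3) < 5 Å turn detection, R_g and Kirkwood R_h.

Since no microsecond trajectories ship with the package, a first-class
synthetic-data module generates multi-copy heptad-repeat systems by
Metropolis Monte Carlo with *planted* square-well attractions, so every
analysis is validated against known ground truth (null calibration,
monotone signal recovery).  See `docs/methods.md` for the model, its
assumptions and its limits.

## Worked example

```python
import ctdkit as ck
from ctdkit.enrichment import composition, enrichment_with_se

# a crowded 4-copy system of 10 wild-type heptads with a planted
# Tyr-Pro attraction of 1.5 kT in a 7 nm periodic box
spec = ck.SyntheticSystemSpec(sequence=ck.generate_heptad_sequence(10),
                              n_copies=4, box_edge_A=70.0, seed=11)
pot = ck.PairPotential.from_pairs({("Y", "P"): 1.5})
traj = ck.mc_sample_system(spec, pot)

table = ck.contact_frequencies(traj, 0.0, traj.times_ps[-1], 1000.0,
                               scope="inter", cutoff_A=5.5, atom_filter=("CB",))
prof = composition([c.sequence for c in traj.topology.chains])
df = enrichment_with_se(table, traj.topology, prof)
print(df[df.type_b == "Y"][["type_a", "type_b", "ratio", "ratio_se"]])
```

prints (seed 11):

```
  type_a type_b     ratio  ratio_se
3      P      Y  2.193587  0.159182
6      S      Y  1.093456  0.185959
8      T      Y  1.162832  0.228098
9      Y      Y  1.658559  0.474241
```

The planted Tyr–Pro attraction is recovered as a ~2.2× enrichment over
the composition background, many standard errors above 1, while
tyrosine's contacts with serine and threonine stay within noise of 1 —
the sign of a specific interaction rather than general stickiness.  (A
single run is noisy; the calibration studies in `ctdkit.studies` pool
six independent replicas.)  In the same spirit
`ck.box_concentration(10, 20.0)` returns `2.076` mM, the effective
protein concentration of ten chains in a 20 nm cubic box.

The numbered scripts under `analysis/` run the full story — construct
characterization, system generation, enrichment calibration/recovery,
stable-pair clustering, and the ensemble-reweighting loop — writing
their tables under `results/`.  The `ctdkit` command-line tool exposes
the same stages (`ctdkit run-all`, `ctdkit contacts`, `ctdkit reweight`,
`ctdkit concentration 10 20`, ...).

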