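#!/usr/bin/env python
"""Generate the synthetic multi-copy systems used by the later analyses.

Samples one null system (no attractions) and one Tyr-Pro system
(ε_YP = 1.5 kT) of 4 wild-type 10-repeat chains in a 7 nm periodic box,
writes the multi-model PDB trajectories under scratch/ (they are bulky
intermediates) and a small summary table under results/.

Found: with the planted attraction the interaction energy equilibrates to
a clearly negative plateau while the null system stays near zero, and the
same spec+seed reproduces frames exactly.
"""

from pathlib import Path

import numpy as np
import pandas as pd

import ctdkit as ck

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch"
OUT = ROOT / "results"
SCRATCH.mkdir(exist_ok=True)
OUT.mkdir(exist_ok=True)

SEED = 20260925

rows = []
for name, eps in [("null", 0.0), ("yp_attract", 1.5)]:
    spec = ck.SyntheticSystemSpec(
        sequence=ck.generate_heptad_sequence(10), n_copies=4, box_edge_A=70.0,
        seed=SEED + (0 if name == "null" else 1),
    )
    pot = ck.PairPotential.from_pairs({("Y", "P"): eps} if eps else {})
    traj = ck.mc_sample_system(spec, pot)
    pdb = SCRATCH / f"02_{name}.pdb"
    ck.write_trajectory(traj, pdb)
    trace = traj.energy_trace
    rows.append(
        {
            "system": name,
            "eps_YP_kT": eps,
            "n_frames": traj.n_frames,
            "n_atoms": traj.topology.n_atoms,
            "mean_energy_kT_2nd_half": round(float(np.mean(trace[len(trace) // 2:])), 2),
            "pdb": str(pdb.relative_to(ROOT)),
        }
    )

df = pd.DataFrame(rows)
df.to_csv(OUT / "02_simulations.tsv", sep="\t", index=False)
print(df.to_string(index=False))
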