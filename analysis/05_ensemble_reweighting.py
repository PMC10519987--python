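#!/usr/bin/env python
"""Ensemble observables and maximum-entropy reweighting on synthetic data.

Builds a 40-conformer self-avoiding-walk ensemble of a 26-repeat chain,
extracts 21-mer repeat fragments, computes turn fractions, R_g and
Kirkwood R_h, checks NOE-style upper bounds, and closes the reweighting
loop: observables generated under known (planted) conformer weights are
refined over the θ grid and the fit/regularization trade-off is recorded.

Found: S_KL decreases and χ² increases monotonically along θ ∈
{1, 10, 25, 100}; at small θ the reweighted averages match the planted
targets to well within one σ.
"""

from pathlib import Path

import numpy as np
import pandas as pd

import ctdkit as ck
from ctdkit.ensemble import extract_fragments, maxent_reweight, noe_satisfaction
from ctdkit.pipeline import AnalysisConfig, run_ensemble_analysis

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results"
OUT.mkdir(exist_ok=True)

SEED = 55

ens = ck.random_conformer_ensemble(ck.generate_heptad_sequence(26), 40, seed=SEED)

frags = extract_fragments(ens, motif="YSPTSPS", length=21,
                          max_fragments=200, seed=SEED)
print(f"extracted {frags.n_conformers} 21-mer fragments "
      f"({frags.trajectory.topology.chains[0].sequence[:14]}...)")

rng = np.random.default_rng(SEED)
w_true = rng.dirichlet(np.ones(ens.n_conformers))
obs = ck.synth_observables(ens, w_true, noise_sd=0.2, seed=SEED, n_distances=8)

cfg = AnalysisConfig(thetas=[1.0, 10.0, 25.0, 100.0])
bundle = run_ensemble_analysis(ens, cfg, OUT / "05_bundle", observables=obs)

summary = pd.read_csv(OUT / "05_bundle" / "reweight_summary.tsv", sep="\t")
print(summary.to_string(index=False))

res_small = maxent_reweight(obs, theta=0.01)
resid = np.abs(res_small.weights @ obs.predicted - obs.experimental) / obs.sigma
print(f"theta=0.01 recovery: max |resid|/sigma = {resid.max():.3f}")

restraints = [
    # sequential CA-CA: always close, must match
    ck.NOERestraint(res_a=1, atoms_a=("CA",), res_b=2, atoms_b=("CA",), upper_bound_A=5.65),
    # i,i+3 at the standard bound: satisfied only by compact sub-ensembles
    ck.NOERestraint(res_a=1, atoms_a=("CA",), res_b=4, atoms_b=("CA",), upper_bound_A=5.65),
    # long-range at the standard bound: unmatched in a SAW ensemble
    ck.NOERestraint(res_a=1, atoms_a=("CA",), res_b=15, atoms_b=("CA",), upper_bound_A=5.65),
]
matched, report = noe_satisfaction(ens, restraints)
report.to_csv(OUT / "05_noe_report.tsv", sep="\t", index=False)
print(f"NOE-style bounds matched: {matched}/{len(restraints)}")
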