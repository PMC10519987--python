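#!/usr/bin/env python
"""Contact-type enrichment: null calibration and planted-signal recovery.

Reruns the pooled-replica studies: a null system (all well depths zero), a
planted Tyr-Pro attraction over the ε grid {0.5, 1.0, 1.5} kT, and the
position-specific variant where only position-1 Tyr and position-6 Pro
attract.  Writes the enrichment tables and the 7×7 heptad-position matrix
under results/.

Found (seed 11): the null system's type-pair enrichment ratios are all
statistically compatible with 1 (|z| < 3); the Y-P ratio rises
monotonically with the planted well depth and is the largest ratio of any
type pair at every ε; the heptad matrix peaks at position pair (1,6).
"""

from pathlib import Path

import numpy as np
import pandas as pd

from ctdkit.studies import (
    heptad_planted_study,
    null_enrichment_study,
    planted_enrichment_study,
)

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

SEED = 11

null_df = null_enrichment_study(master_seed=SEED)
null_df.to_csv(OUT / "03_null_enrichment.tsv", sep="\t", index=False)
print("null system: max |z| =", round(null_df["z"].abs().max(), 2))

planted = planted_enrichment_study(master_seed=SEED)
planted.to_csv(OUT / "03_planted_enrichment.tsv", sep="\t", index=False)
print(planted.to_string(index=False))

hm = heptad_planted_study(master_seed=SEED)
hm.to_dataframe().to_csv(OUT / "03_heptad_matrix.tsv", sep="\t")
p, q = np.unravel_index(np.nanargmax(hm.ratios), (7, 7))
print(f"heptad matrix maximum at positions ({p + 1},{q + 1}), "
      f"ratio {np.nanmax(hm.ratios):.2f}")
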