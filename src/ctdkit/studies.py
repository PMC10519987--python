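"""Canned study designs over the synthetic multi-copy systems.

These encode the package's reference conditions for the calibration and
recovery studies: wild-type heptad chains of 10 repeats, 4 copies in a
7 nm periodic box, square wells of range 5.5 Å on the CB interaction
sites, and 6 pooled independent replicas of 25 well-separated frames
each (the replicas, not frames within a run, carry most of the
cluster-history variance).  Contacts in
these coarse systems are measured between CB pseudo-atoms at the well
range, which makes the null model exactly type-exchangeable and a contact
identical to an occupied interaction well (see docs/methods.md).
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .contacts import ContactTable, contact_frequencies, merge_contact_tables
from .enrichment import composition, enrichment_with_se, heptad_position_matrix
from .model import Topology
from .sequence import annotate_heptads
from .synthetic import PairPotential, SyntheticSystemSpec, generate_heptad_sequence, mc_sample_system

__all__ = [
    "STUDY_N_REPEATS",
    "STUDY_N_COPIES",
    "STUDY_BOX_A",
    "STUDY_WELL_RANGE_A",
    "STUDY_N_REPLICAS",
    "sample_pooled_contacts",
    "null_enrichment_study",
    "planted_enrichment_study",
    "heptad_planted_study",
]

STUDY_N_REPEATS = 10
STUDY_N_COPIES = 4
STUDY_BOX_A = 70.0
STUDY_WELL_RANGE_A = 5.5
STUDY_N_REPLICAS = 6
STUDY_SAMPLE_STRIDE = 40  # sweeps between frames: decorrelates cluster history


def _study_sequence() -> str:
    return generate_heptad_sequence(STUDY_N_REPEATS)


def sample_pooled_contacts(
    eps_pairs: dict,
    master_seed: int,
    n_replicas: int = STUDY_N_REPLICAS,
    labels: Optional[Sequence[str]] = None,
) -> tuple[ContactTable, Topology]:
    """Pooled intermolecular CB-contact statistics over MC replicas."""
    rng = np.random.default_rng(master_seed)
    potential = PairPotential.from_pairs(eps_pairs, well_range_A=STUDY_WELL_RANGE_A)
    tables = []
    topology = None
    for _ in range(n_replicas):
        spec = SyntheticSystemSpec(
            sequence=_study_sequence(),
            n_copies=STUDY_N_COPIES,
            box_edge_A=STUDY_BOX_A,
            sample_stride=STUDY_SAMPLE_STRIDE,
            seed=int(rng.integers(2 ** 31)),
        )
        traj = mc_sample_system(spec, potential, labels=labels)
        tables.append(
            contact_frequencies(
                traj, 0.0, float(traj.times_ps[-1]), 1000.0, scope="inter",
                cutoff_A=STUDY_WELL_RANGE_A, atom_filter=("CB",),
            )
        )
        topology = traj.topology
    return merge_contact_tables(tables), topology


def null_enrichment_study(master_seed: int) -> pd.DataFrame:
    """Calibration: with no planted attraction every type-pair enrichment
    ratio should be statistically compatible with 1."""
    table, top = sample_pooled_contacts({}, master_seed)
    profile = composition([c.sequence for c in top.chains])
    df = enrichment_with_se(table, top, profile)
    df["z"] = (df["ratio"] - 1.0) / df["ratio_se"]
    return df


def planted_enrichment_study(
    master_seed: int, eps_grid: Sequence[float] = (0.5, 1.0, 1.5)
) -> pd.DataFrame:
    """Recovery: Tyr-Pro enrichment vs planted well depth.

    Returns one row per ε with the Y-P ratio, its SE, and the maximal
    ratio over all type pairs (for the specificity check).
    """
    profile = composition([_study_sequence()] * STUDY_N_COPIES)
    rows = []
    for k, eps in enumerate(eps_grid):
        table, top = sample_pooled_contacts(
            {("Y", "P"): eps}, master_seed + 1 + k
        )
        df = enrichment_with_se(table, top, profile)
        yp = df[(df["type_a"] == "P") & (df["type_b"] == "Y")].iloc[0]
        best = df.loc[df["ratio"].idxmax()]
        rows.append(
            {"eps_kT": eps, "yp_ratio": yp["ratio"], "yp_ratio_se": yp["ratio_se"],
             "max_pair": f"{best['type_a']}-{best['type_b']}",
             "max_ratio": best["ratio"],
             "n_events": int(sum(table.counts.values()))}
        )
    return pd.DataFrame(rows)


def heptad_planted_study(master_seed: int, eps: float = 1.5, n_replicas: int = 2):
    """Position-specific recovery: attraction only between position-1 Tyr
    and position-6 Pro must put the heptad-matrix maximum at (1, 6)."""
    seq = _study_sequence()
    ann = annotate_heptads(seq)
    labels = []
    for i, ch in enumerate(seq):
        if ch == "Y" and ann.heptad_position[i] == 1:
            labels.append("Y1")
        elif ch == "P" and ann.heptad_position[i] == 6:
            labels.append("P6")
        else:
            labels.append(ch)
    table, top = sample_pooled_contacts(
        {("Y1", "P6"): eps}, master_seed, n_replicas=n_replicas,
        labels=labels * STUDY_N_COPIES,
    )
    return heptad_position_matrix(table, top, ann)
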