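"""Residue-residue distance matrices, contact maps and contact statistics.

A contact is a residue pair whose minimum interatomic distance lies within
the cutoff (3.5 Å by default, matching all-atom condensate simulations;
comparison is inclusive).  When a frame carries an orthorhombic box, every
atom-pair distance is the minimum-image distance, so contacts across
periodic images count — the crowded multi-copy box is periodic.

Contact frequencies are computed over an analysis window sampled on a
stride grid anchored at the window start (both endpoints included when
on-grid); the reference analysis uses the last 0.3 µs of a trajectory at a
1 ns stride.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, NamedTuple, Optional

import numpy as np
import pandas as pd

from .model import Frame, Topology, Trajectory, ValidationError

__all__ = [
    "ContactKey",
    "ContactTable",
    "InteractivityProfile",
    "min_image_diff",
    "min_residue_distance",
    "residue_min_distance_matrix",
    "contact_map",
    "contact_frequencies",
    "interactivity_profile",
    "partners_per_conformer",
]

Scope = Literal["intra", "inter"]
# 'all', 'heavy', or an explicit sequence of atom names (selection-style)
AtomFilter = "str | Sequence[str]"


class ContactKey(NamedTuple):
    """Canonically ordered undirected residue pair ((chain, res) sorted)."""

    chain_a: str
    res_a: int
    chain_b: str
    res_b: int

    @classmethod
    def make(cls, chain_a: str, res_a: int, chain_b: str, res_b: int) -> "ContactKey":
        if (chain_a, res_a) == (chain_b, res_b):
            raise ValidationError("self-pairs are not valid contact keys")
        if (chain_a, res_a) <= (chain_b, res_b):
            return cls(chain_a, res_a, chain_b, res_b)
        return cls(chain_b, res_b, chain_a, res_a)


def min_image_diff(delta: np.ndarray, box: Optional[np.ndarray]) -> np.ndarray:
    """Apply the orthorhombic minimum-image convention to displacement(s)."""
    if box is None:
        return delta
    return delta - box * np.round(delta / box)


def _atom_selection(topology: Topology, atom_filter) -> np.ndarray:
    """Boolean atom mask: 'all', 'heavy', or an explicit atom-name selection."""
    if isinstance(atom_filter, str):
        if atom_filter == "all":
            return np.ones(topology.n_atoms, dtype=bool)
        if atom_filter == "heavy":
            return topology.atom_is_heavy.copy()
        atom_filter = (atom_filter,)
    try:
        names = list(atom_filter)
    except TypeError:
        raise ValidationError(f"unknown atom_filter {atom_filter!r}")
    return np.isin(topology.atom_names, names)


def residue_min_distance_matrix(
    frame: Frame,
    topology: Topology,
    atom_filter: AtomFilter = "all",
    use_pbc: bool = True,
) -> np.ndarray:
    """(n_res, n_res) matrix of minimum interatomic distances (Å).

    Atoms are laid out residue-contiguously in the topology, so the
    all-atom distance matrix reduces to residue pairs with two
    ``minimum.reduceat`` passes.
    """
    mask = _atom_selection(topology, atom_filter)
    res_of = topology.atom_residue[mask]
    counts = np.bincount(res_of, minlength=topology.n_residues)
    if np.any(counts == 0):
        empty = np.flatnonzero(counts == 0)
        raise ValidationError(
            f"residues with no atoms after filter {atom_filter!r}: {empty.tolist()}"
        )
    coords = frame.coords[mask]
    box = frame.box if use_pbc else None
    if use_pbc and frame.box is None:
        box = None  # no box recorded: plain Euclidean distances

    d2 = np.zeros((coords.shape[0], coords.shape[0]))
    for ax in range(3):
        delta = coords[:, ax, None] - coords[None, :, ax]
        if box is not None:
            delta -= box[ax] * np.round(delta / box[ax])
        d2 += delta * delta
    starts = np.concatenate(([0], np.cumsum(counts)[:-1]))
    red = np.minimum.reduceat(d2, starts, axis=0)
    red = np.minimum.reduceat(red, starts, axis=1)
    return np.sqrt(red)


def min_residue_distance(
    frame: Frame,
    topology: Topology,
    res_a: tuple[str, int],
    res_b: tuple[str, int],
    atom_filter: AtomFilter = "all",
    use_pbc: bool = True,
) -> float:
    """Minimum over atom pairs of the (minimum-image) Euclidean distance."""
    mask = _atom_selection(topology, atom_filter)
    ia = topology.residue_atom_indices(topology.flat_residue_id(*res_a))
    ib = topology.residue_atom_indices(topology.flat_residue_id(*res_b))
    ia = ia[mask[ia]]
    ib = ib[mask[ib]]
    if ia.size == 0 or ib.size == 0:
        raise ValidationError("residue has no atoms after filter")
    delta = frame.coords[ia][:, None, :] - frame.coords[ib][None, :, :]
    if use_pbc and frame.box is not None:
        delta = min_image_diff(delta, frame.box)
    return float(np.sqrt((delta ** 2).sum(axis=-1)).min())


def contact_map(
    frame: Frame,
    topology: Topology,
    cutoff_A: float = 3.5,
    scope: Scope = "inter",
    min_seq_sep: int = 2,
    atom_filter: AtomFilter = "all",
    use_pbc: bool = True,
) -> set[ContactKey]:
    """Residue pairs whose minimum interatomic distance is ≤ cutoff (inclusive).

    ``intra`` scope keeps same-chain pairs at sequence separation
    ≥ ``min_seq_sep`` (default 2: i,i±1 contacts are bond-forced);
    ``inter`` keeps different-chain pairs.
    """
    if cutoff_A <= 0:
        raise ValidationError("cutoff must be positive")
    dmat = residue_min_distance_matrix(frame, topology, atom_filter, use_pbc)
    n = topology.n_residues
    iu, ju = np.triu_indices(n, k=1)
    hit = dmat[iu, ju] <= cutoff_A
    iu, ju = iu[hit], ju[hit]
    rchain = topology.residue_chain
    rindex = topology.residue_index
    same_chain = rchain[iu] == rchain[ju]
    if scope == "intra":
        keep = same_chain & (np.abs(rindex[iu] - rindex[ju]) >= min_seq_sep)
    elif scope == "inter":
        keep = ~same_chain
    else:
        raise ValidationError(f"unknown scope {scope!r}")
    chain_ids = [c.chain_id for c in topology.chains]
    return {
        ContactKey.make(
            chain_ids[rchain[i]], int(rindex[i]), chain_ids[rchain[j]], int(rindex[j])
        )
        for i, j in zip(iu[keep], ju[keep])
    }


@dataclass
class ContactTable:
    """Per residue-pair contact counts over an analysis window.

    ``per_frame`` retains the contact set of each analyzed frame so that
    per-frame statistics (interactivity, partner counts) stay exact.
    """

    scope: Scope
    window_start_ps: float
    window_end_ps: float
    stride_ps: float
    n_frames_analyzed: int
    counts: dict[ContactKey, int] = field(default_factory=dict)
    per_frame: list[frozenset] = field(default_factory=list)

    @property
    def frequencies(self) -> dict[ContactKey, float]:
        return {k: c / self.n_frames_analyzed for k, c in self.counts.items()}

    def to_dataframe(self, topology: Topology) -> pd.DataFrame:
        rows = []
        for key, count in sorted(self.counts.items()):
            ra = topology.residue(key.chain_a, key.res_a)
            rb = topology.residue(key.chain_b, key.res_b)
            rows.append(
                {
                    "chain_a": key.chain_a,
                    "res_a": key.res_a,
                    "name_a": ra.name3,
                    "chain_b": key.chain_b,
                    "res_b": key.res_b,
                    "name_b": rb.name3,
                    "count": count,
                    "n_frames": self.n_frames_analyzed,
                    "frequency": count / self.n_frames_analyzed,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "chain_a", "res_a", "name_a", "chain_b", "res_b", "name_b",
                "count", "n_frames", "frequency",
            ],
        )

    def to_tsv(self, path: str, topology: Topology) -> None:
        self.to_dataframe(topology).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str, scope: Scope = "inter") -> "ContactTable":
        """Rebuild aggregate counts from a serialized table.

        Per-frame contact sets are not serialized, so frame-resolved
        statistics (interactivity, partner counts) are unavailable on a
        table read back from TSV.
        """
        df = pd.read_csv(path, sep="\t")
        if df.empty:
            raise ValidationError(f"{path}: empty contact table")
        n_frames = int(df["n_frames"].iloc[0])
        counts = {
            ContactKey.make(str(r.chain_a), int(r.res_a), str(r.chain_b), int(r.res_b)): int(r["count"])
            for r in df.itertuples()
        }
        return cls(
            scope=scope, window_start_ps=0.0, window_end_ps=0.0, stride_ps=0.0,
            n_frames_analyzed=n_frames, counts=counts, per_frame=[],
        )


def merge_contact_tables(tables: "list[ContactTable]") -> "ContactTable":
    """Pool contact statistics over independent replicas of one system.

    Tables must share scope; counts add, per-frame contact sets concatenate,
    frequencies become pooled-frame frequencies.
    """
    if not tables:
        raise ValidationError("no tables to merge")
    scope = tables[0].scope
    if any(t.scope != scope for t in tables):
        raise ValidationError("cannot merge tables with different scopes")
    counts: dict[ContactKey, int] = {}
    per_frame: list[frozenset] = []
    for t in tables:
        for k, c in t.counts.items():
            counts[k] = counts.get(k, 0) + c
        per_frame.extend(t.per_frame)
    return ContactTable(
        scope=scope,
        window_start_ps=tables[0].window_start_ps,
        window_end_ps=tables[-1].window_end_ps,
        stride_ps=tables[0].stride_ps,
        n_frames_analyzed=sum(t.n_frames_analyzed for t in tables),
        counts=counts,
        per_frame=per_frame,
    )


def _window_frames(
    trajectory: Trajectory,
    window_start_ps: float,
    window_end_ps: float,
    stride_ps: float,
) -> list[int]:
    if window_end_ps < window_start_ps:
        raise ValidationError("window end precedes window start")
    if stride_ps <= 0:
        raise ValidationError("stride must be positive")
    times = trajectory.times_ps
    if times.size == 0:
        raise ValidationError("trajectory has no frames")
    if window_start_ps < times[0] - 1e-9 or window_end_ps > times[-1] + 1e-9:
        raise ValidationError(
            f"window [{window_start_ps}, {window_end_ps}] ps outside trajectory "
            f"time range [{times[0]}, {times[-1]}] ps"
        )
    grid = np.arange(window_start_ps, window_end_ps + 0.5 * stride_ps, stride_ps)
    grid = grid[grid <= window_end_ps + 1e-9]
    idx = []
    for t in grid:
        hits = np.flatnonzero(np.isclose(times, t, atol=1e-6))
        if hits.size:
            idx.append(int(hits[0]))
    if not idx:
        raise ValidationError("no trajectory frames on the window/stride grid")
    return idx


def contact_frequencies(
    trajectory: Trajectory,
    window_start_ps: float,
    window_end_ps: float,
    stride_ps: float = 1000.0,
    scope: Scope = "inter",
    cutoff_A: float = 3.5,
    min_seq_sep: int = 2,
    atom_filter: AtomFilter = "all",
    use_pbc: bool = True,
) -> ContactTable:
    """Contact frequency per residue pair: frames-in-contact / frames-analyzed."""
    idx = _window_frames(trajectory, window_start_ps, window_end_ps, stride_ps)
    counts: dict[ContactKey, int] = {}
    per_frame: list[frozenset] = []
    for i in idx:
        cm = contact_map(
            trajectory.frames[i],
            trajectory.topology,
            cutoff_A=cutoff_A,
            scope=scope,
            min_seq_sep=min_seq_sep,
            atom_filter=atom_filter,
            use_pbc=use_pbc,
        )
        per_frame.append(frozenset(cm))
        for key in cm:
            counts[key] = counts.get(key, 0) + 1
    return ContactTable(
        scope=scope,
        window_start_ps=window_start_ps,
        window_end_ps=window_end_ps,
        stride_ps=stride_ps,
        n_frames_analyzed=len(idx),
        counts=counts,
        per_frame=per_frame,
    )


@dataclass
class InteractivityProfile:
    """Per residue position: mean per-frame probability of ≥1 intermolecular
    contact, averaged over the molecule copies."""

    values: np.ndarray
    per_copy: dict[str, np.ndarray]


def _require_inter(table: ContactTable) -> None:
    if table.scope != "inter":
        raise ValidationError("an intermolecular ContactTable is required")
    if not table.per_frame:
        raise ValidationError("ContactTable lacks per-frame contact sets")


def interactivity_profile(table: ContactTable, topology: Topology) -> InteractivityProfile:
    """Residue interactivity along the species sequence (Fig.-7c style)."""
    _require_inter(table)
    if not topology.single_species():
        raise ValidationError("interactivity profile requires a single species")
    length = len(topology.chains[0].residues)
    pos_of = {
        c.chain_id: {r.index: k for k, r in enumerate(c.residues)}
        for c in topology.chains
    }
    n_frames = len(table.per_frame)
    per_copy = {c.chain_id: np.zeros(length) for c in topology.chains}
    for fset in table.per_frame:
        touched: dict[str, set[int]] = {cid: set() for cid in per_copy}
        for key in fset:
            touched[key.chain_a].add(pos_of[key.chain_a][key.res_a])
            touched[key.chain_b].add(pos_of[key.chain_b][key.res_b])
        for cid, positions in touched.items():
            for p in positions:
                per_copy[cid][p] += 1.0
    for cid in per_copy:
        per_copy[cid] /= n_frames
    values = np.mean(np.stack(list(per_copy.values())), axis=0)
    return InteractivityProfile(values=values, per_copy=per_copy)


def partners_per_conformer(table: ContactTable, topology: Topology) -> float:
    """Mean number of distinct partner chains per copy per frame."""
    _require_inter(table)
    chain_ids = [c.chain_id for c in topology.chains]
    n_frames = len(table.per_frame)
    total = 0.0
    for fset in table.per_frame:
        partners: dict[str, set[str]] = {cid: set() for cid in chain_ids}
        for key in fset:
            partners[key.chain_a].add(key.chain_b)
            partners[key.chain_b].add(key.chain_a)
        total += sum(len(s) for s in partners.values())
    return total / (n_frames * len(chain_ids))
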