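"""Stable-pair selection, master trajectories, ring-distance distributions
and GROMOS-style RMSD clustering of two-residue configurations.

Stable pairs are residue pairs in contact for more than a frequency
threshold (10% of the analysis window by default).  For each stable pair,
snapshots are pooled at a fixed spacing (10 ns by default) into a *master
trajectory* of two-residue configurations, which is then clustered with
the greedy neighbor-count algorithm of the GROMOS cluster tool: the
configuration with the most neighbors within an RMSD cutoff seeds a
cluster, the cluster is removed, and the procedure repeats.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .contacts import ContactKey, ContactTable, min_image_diff
from .model import Frame, Topology, Trajectory, ValidationError

__all__ = [
    "PairConfiguration",
    "MasterTrajectory",
    "ClusterResult",
    "DistanceHistogram",
    "stable_pairs",
    "residue_cog",
    "ring_cog_distance",
    "build_master_trajectory",
    "pair_rmsd",
    "rmsd_matrix",
    "gromos_cluster",
    "occupancy_curve",
    "distance_distribution",
]

TYR_SIDECHAIN_HEAVY = ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH")

AtomScope = Literal["all", "heavy"]


def stable_pairs(table: ContactTable, threshold: float = 0.10) -> list[ContactKey]:
    """Pairs with contact frequency strictly greater than the threshold,
    sorted by descending frequency (ties by key)."""
    if not 0 <= threshold < 1:
        raise ValidationError("threshold must lie in [0, 1)")
    freqs = table.frequencies
    keep = [(k, f) for k, f in freqs.items() if f > threshold]
    keep.sort(key=lambda kv: (-kv[1], kv[0]))
    return [k for k, _ in keep]


def _cog_selection(topology: Topology, flat_res: int) -> np.ndarray:
    """Atom indices entering a residue's center of geometry.

    Pro: all heavy atoms of the complete residue; Tyr: side-chain heavy
    atoms (ring + CB + OH); any other residue: all heavy atoms.
    """
    res_row = flat_res
    name1 = topology.residue_name1[res_row]
    idx = topology.residue_atom_indices(res_row, heavy_only=True)
    if name1 == "Y":
        names = topology.atom_names[idx]
        sel = idx[np.isin(names, TYR_SIDECHAIN_HEAVY)]
        missing = sorted(set(TYR_SIDECHAIN_HEAVY) - set(map(str, names)))
        if missing:
            raise ValidationError(f"Tyr residue missing ring atoms: {missing}")
        return sel
    return idx


def residue_cog(frame: Frame, topology: Topology, res: tuple[str, int]) -> np.ndarray:
    """Unweighted centroid of the residue's COG atom selection."""
    flat = topology.flat_residue_id(*res)
    sel = _cog_selection(topology, flat)
    if sel.size == 0:
        raise ValidationError(f"residue {res} has no heavy atoms")
    return frame.coords[sel].mean(axis=0)


def ring_cog_distance(
    frame: Frame,
    topology: Topology,
    pro_res: tuple[str, int],
    tyr_res: tuple[str, int],
) -> float:
    """Distance between the Pro-residue COG (all heavy atoms) and the Tyr
    side-chain ring COG; minimum-image when the frame has a box."""
    if topology.residue(*pro_res).name1 != "P":
        raise ValidationError(f"residue {pro_res} is not a proline")
    if topology.residue(*tyr_res).name1 != "Y":
        raise ValidationError(f"residue {tyr_res} is not a tyrosine")
    cog_p = residue_cog(frame, topology, pro_res)
    cog_y = residue_cog(frame, topology, tyr_res)
    delta = min_image_diff(cog_y - cog_p, frame.box)
    return float(np.linalg.norm(delta))


@dataclass
class PairConfiguration:
    """Coordinates of one two-residue configuration plus provenance."""

    coords: np.ndarray          # (n_atoms, 3), residue a then residue b
    atom_names: tuple[str, ...]
    atom_is_heavy: np.ndarray
    separation: float           # COG distance, Å
    time_ps: float
    pair: ContactKey

    def scope_index(self, atom_scope: AtomScope) -> np.ndarray:
        if atom_scope == "all":
            return np.arange(len(self.atom_names))
        return np.flatnonzero(self.atom_is_heavy)


@dataclass
class MasterTrajectory:
    """Pooled fixed-spacing two-residue configurations for a set of pairs."""

    configurations: list[PairConfiguration]
    spacing_ps: float
    pairs: list[ContactKey] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.configurations)

    @property
    def separations(self) -> np.ndarray:
        return np.asarray([c.separation for c in self.configurations])


def _extract_pair_configuration(
    frame: Frame, topology: Topology, key: ContactKey
) -> PairConfiguration:
    # order the two residues by type so that e.g. every Pro-Tyr
    # configuration shares one atom template regardless of chain labels
    na = topology.residue(key.chain_a, key.res_a).name1
    nb = topology.residue(key.chain_b, key.res_b).name1
    if (nb, key.chain_b, key.res_b) < (na, key.chain_a, key.res_a):
        key = ContactKey(key.chain_b, key.res_b, key.chain_a, key.res_a)
    fa = topology.flat_residue_id(key.chain_a, key.res_a)
    fb = topology.flat_residue_id(key.chain_b, key.res_b)
    ia = topology.residue_atom_indices(fa)
    ib = topology.residue_atom_indices(fb)
    ca = frame.coords[ia].copy()
    cb = frame.coords[ib].copy()
    cog_a = frame.coords[_cog_selection(topology, fa)].mean(axis=0)
    cog_b = frame.coords[_cog_selection(topology, fb)].mean(axis=0)
    if frame.box is not None:
        # bring residue b into the periodic image nearest residue a, rigidly
        shift = frame.box * np.round((cog_b - cog_a) / frame.box)
        cb -= shift
        cog_b = cog_b - shift
    names = tuple(map(str, np.concatenate([topology.atom_names[ia], topology.atom_names[ib]])))
    heavy = np.concatenate([topology.atom_is_heavy[ia], topology.atom_is_heavy[ib]])
    return PairConfiguration(
        coords=np.vstack([ca, cb]),
        atom_names=names,
        atom_is_heavy=heavy,
        separation=float(np.linalg.norm(cog_b - cog_a)),
        time_ps=frame.time_ps,
        pair=key,
    )


def build_master_trajectory(
    trajectory: Trajectory,
    pairs: Sequence[ContactKey],
    window_start_ps: float,
    window_end_ps: float,
    spacing_ps: float = 10000.0,
) -> MasterTrajectory:
    """Pool snapshots at ``window_start + k*spacing`` for k with the snapshot
    time strictly inside [start, end) — a 0.3 µs window at 10 ns spacing
    yields exactly 30 snapshots per pair."""
    if not pairs:
        raise ValidationError("no pairs given")
    if spacing_ps <= 0:
        raise ValidationError("spacing must be positive")
    times = trajectory.times_ps
    if window_end_ps <= window_start_ps:
        grid = np.array([window_start_ps])  # degenerate single-frame window
    else:
        grid = np.arange(window_start_ps, window_end_ps - 1e-9, spacing_ps)
    frame_idx = []
    for t in grid:
        hits = np.flatnonzero(np.isclose(times, t, atol=1e-6))
        if hits.size == 0:
            raise ValidationError(
                f"snapshot grid time {t} ps is off the trajectory frame grid"
            )
        frame_idx.append(int(hits[0]))
    configs: list[PairConfiguration] = []
    for key in pairs:
        for i in frame_idx:
            configs.append(
                _extract_pair_configuration(trajectory.frames[i], trajectory.topology, key)
            )
    return MasterTrajectory(configurations=configs, spacing_ps=spacing_ps, pairs=list(pairs))


def pair_rmsd(
    a: PairConfiguration,
    b: PairConfiguration,
    atom_scope: AtomScope = "all",
    superpose: bool = True,
) -> float:
    """RMSD after optimal least-squares superposition (proper rotations only,
    so mirror images never match)."""
    if a.atom_names != b.atom_names:
        raise ValidationError("configurations have different atom templates")
    sel = a.scope_index(atom_scope)
    xa = a.coords[sel]
    xb = b.coords[sel]
    xa = xa - xa.mean(axis=0)
    xb = xb - xb.mean(axis=0)
    if not superpose:
        return float(np.sqrt(((xa - xb) ** 2).sum(axis=1).mean()))
    _, rssd = Rotation.align_vectors(xa, xb)
    return float(rssd / np.sqrt(sel.size))


def rmsd_matrix(
    configs: Sequence[PairConfiguration], atom_scope: AtomScope = "all"
) -> np.ndarray:
    n = len(configs)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = pair_rmsd(configs[i], configs[j], atom_scope)
    return mat


@dataclass
class ClusterResult:
    """Exhaustive partition of configurations into RMSD clusters."""

    rmsd_cutoff: float
    clusters: list[dict]  # {"center": id, "members": [ids], "population": fraction}

    @property
    def populations(self) -> np.ndarray:
        return np.asarray([c["population"] for c in self.clusters])

    @property
    def top_population(self) -> float:
        return float(self.populations[0]) if self.clusters else 0.0


def gromos_cluster(
    master: MasterTrajectory | Sequence[PairConfiguration],
    rmsd_cutoff: float,
    atom_scope: AtomScope = "all",
    precomputed: Optional[np.ndarray] = None,
) -> ClusterResult:
    """Greedy neighbor-count clustering (GROMOS scheme).

    Repeatedly: the configuration with the most neighbors within the RMSD
    cutoff (inclusive) becomes a cluster center; it and its neighbors form
    a cluster and are removed.  Ties go to the lowest configuration id.
    Clusters are reported by non-increasing size.
    """
    configs = master.configurations if isinstance(master, MasterTrajectory) else list(master)
    if not configs:
        raise ValidationError("no configurations to cluster")
    if rmsd_cutoff <= 0:
        raise ValidationError("RMSD cutoff must be positive")
    mat = rmsd_matrix(configs, atom_scope) if precomputed is None else precomputed
    n = len(configs)
    adj = mat <= rmsd_cutoff
    np.fill_diagonal(adj, False)
    remaining = np.ones(n, dtype=bool)
    clusters = []
    while remaining.any():
        counts = (adj & remaining[None, :]).sum(axis=1)
        counts[~remaining] = -1
        center = int(np.argmax(counts))  # argmax takes the lowest index on ties
        members = np.flatnonzero(adj[center] & remaining).tolist()
        cluster_ids = sorted([center] + members)
        clusters.append({"center": center, "members": cluster_ids})
        remaining[cluster_ids] = False
    clusters.sort(key=lambda c: (-len(c["members"]), c["center"]))
    for c in clusters:
        c["population"] = len(c["members"]) / n
    return ClusterResult(rmsd_cutoff=rmsd_cutoff, clusters=clusters)


def occupancy_curve(
    master: MasterTrajectory,
    cutoffs: Sequence[float],
    separation_max_A: float = 20.0,
    atom_scope: AtomScope = "all",
) -> list[tuple[float, float]]:
    """Top-cluster population vs RMSD cutoff.

    Both the clustering and the population denominator use the subset of
    configurations with COG separation strictly below ``separation_max_A``
    (2 nm by default).
    """
    sel = [c for c in master.configurations if c.separation < separation_max_A]
    if not sel:
        raise ValidationError("no configurations below the separation limit")
    mat = rmsd_matrix(sel, atom_scope)
    out = []
    for cutoff in cutoffs:
        result = gromos_cluster(sel, cutoff, atom_scope, precomputed=mat)
        out.append((float(cutoff), result.top_population))
    return out


@dataclass
class DistanceHistogram:
    bin_edges: np.ndarray
    densities: np.ndarray  # normalized: integral over bins = 1


def distance_distribution(
    master: MasterTrajectory, bin_width_A: float = 0.5
) -> DistanceHistogram:
    """Normalized histogram of configuration COG separations."""
    if bin_width_A <= 0:
        raise ValidationError("bin width must be positive")
    seps = master.separations
    if seps.size == 0:
        raise ValidationError("empty master trajectory")
    upper = np.ceil(seps.max() / bin_width_A + 1) * bin_width_A
    edges = np.arange(0.0, upper + 0.5 * bin_width_A, bin_width_A)
    dens, edges = np.histogram(seps, bins=edges, density=True)
    return DistanceHistogram(bin_edges=edges, densities=dens)
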