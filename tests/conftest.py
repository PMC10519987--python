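"""Shared fixtures and independent oracle implementations.

The oracles here are deliberately naive (explicit loops, 27-image scans,
exhaustive enumeration) and never share code with the library paths they
check.
"""

from __future__ import annotations

import numpy as np
import pytest

from ctdkit.contacts import ContactKey
from ctdkit.model import Atom, Chain, Frame, Residue, Topology, Trajectory
from ctdkit.pairgeom import PairConfiguration


# ---------------------------------------------------------------------------
# brute-force oracles


def brute_force_contacts(frame, topology, cutoff, scope, min_seq_sep=2, use_pbc=True):
    """Exhaustive all-atom double loop with an explicit 27-image PBC scan.

    The ±1-image scan presumes coordinates wrapped into the primary box;
    callers wrap their fixtures accordingly (the library path is
    wrap-agnostic through the minimum-image convention).
    """
    box = frame.box if use_pbc else None
    found = set()
    chains = topology.chains
    for i in range(topology.n_residues):
        for j in range(i + 1, topology.n_residues):
            ci, cj = topology.residue_chain[i], topology.residue_chain[j]
            if scope == "inter" and ci == cj:
                continue
            if scope == "intra":
                if ci != cj:
                    continue
                if abs(int(topology.residue_index[i]) - int(topology.residue_index[j])) < min_seq_sep:
                    continue
            ia = topology.residue_atom_indices(i)
            ja = topology.residue_atom_indices(j)
            best = np.inf
            for a in ia:
                for b in ja:
                    d = frame.coords[a] - frame.coords[b]
                    if box is not None:
                        for sx in (-1, 0, 1):
                            for sy in (-1, 0, 1):
                                for sz in (-1, 0, 1):
                                    img = d + box * np.array([sx, sy, sz])
                                    best = min(best, float(np.linalg.norm(img)))
                    else:
                        best = min(best, float(np.linalg.norm(d)))
            if best <= cutoff:
                found.add(
                    ContactKey.make(
                        chains[ci].chain_id, int(topology.residue_index[i]),
                        chains[cj].chain_id, int(topology.residue_index[j]),
                    )
                )
    return found


def brute_force_gromos(rmsd_mat: np.ndarray, cutoff: float):
    """Reference neighbor-count clustering by explicit set bookkeeping."""
    n = rmsd_mat.shape[0]
    remaining = set(range(n))
    clusters = []
    while remaining:
        best_center, best_count = None, -1
        for c in sorted(remaining):
            count = sum(
                1 for other in remaining
                if other != c and rmsd_mat[c, other] <= cutoff
            )
            if count > best_count:
                best_center, best_count = c, count
        members = sorted(
            {best_center}
            | {o for o in remaining if o != best_center and rmsd_mat[best_center, o] <= cutoff}
        )
        clusters.append({"center": best_center, "members": members})
        remaining -= set(members)
    clusters.sort(key=lambda c: (-len(c["members"]), c["center"]))
    for c in clusters:
        c["population"] = len(c["members"]) / n
    return clusters


def grid_search_two_conformer(y, yexp, sigma, theta, w0=(0.5, 0.5), n_grid=200001):
    """1-D simplex grid search for the two-conformer reweighting optimum."""
    w1 = np.linspace(1e-9, 1 - 1e-9, n_grid)
    w = np.stack([w1, 1 - w1], axis=1)
    resid = (w @ np.asarray(y).reshape(2, -1) - np.asarray(yexp)) / np.asarray(sigma)
    chi2 = (resid ** 2).sum(axis=1)
    skl = (w * np.log(w / np.asarray(w0))).sum(axis=1)
    g = 0.5 * chi2 + theta * skl
    k = int(np.argmin(g))
    return w[k], g[k]


# ---------------------------------------------------------------------------
# structure-building helpers


def point_residue(index: int, name3: str = "ALA", atom: str = "CA") -> Residue:
    return Residue(index=index, name3=name3, atoms=[Atom(name=atom)])


def single_atom_system(positions, chain_split=None, box=None, names=None):
    """n single-atom residues at given positions, optionally split into chains."""
    positions = np.asarray(positions, dtype=float)
    n = positions.shape[0]
    chain_split = chain_split or [n]
    names = names or ["ALA"] * n
    chains = []
    k = 0
    for ci, size in enumerate(chain_split):
        residues = [point_residue(i + 1, names[k + i]) for i in range(size)]
        chains.append(Chain(chain_id=chr(ord("A") + ci), residues=residues))
        k += size
    top = Topology(chains)
    top.assign_copy_indices()
    frame = Frame(coords=positions, box=box)
    return top, frame


def make_pair_config(coords, seed_jitter=None, separation=None, time_ps=0.0,
                     pair=None, rng=None):
    coords = np.asarray(coords, dtype=float)
    if seed_jitter is not None:
        coords = coords + rng.normal(scale=seed_jitter, size=coords.shape)
    names = tuple(f"X{i}" for i in range(coords.shape[0]))
    return PairConfiguration(
        coords=coords,
        atom_names=names,
        atom_is_heavy=np.ones(coords.shape[0], dtype=bool),
        separation=float(separation if separation is not None else 0.0),
        time_ps=time_ps,
        pair=pair or ContactKey("A", 1, "B", 1),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def chiral_coords():
    """Four non-coplanar points with a definite handedness."""
    return np.array(
        [[0.0, 0.0, 0.0], [1.5, 0.0, 0.0], [0.0, 1.2, 0.0], [0.3, 0.4, 1.7]]
    )
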