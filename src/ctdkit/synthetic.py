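"""Synthetic heptad-repeat systems with known ground truth.

This module generates everything the analysis operations are exercised
on: heptad-repeat sequences and their variants, coarse pseudo-atom chain
structures, Metropolis Monte-Carlo multi-copy trajectories with *planted*
pair attractions (so contact enrichments have a known sign and ordering),
declarative exact-count contact fixtures, and synthetic observable tables
for reweighting.

The chain model is deliberately coarse: an N/CA/C/O backbone at ideal
spacing plus pseudo side chains (a 6-membered pseudo-ring, OH and CB for
Tyr; ring-completion atoms for Pro; a single CB centroid otherwise).
It exercises every operation of the package — contacts, ring centers of
geometry, RMSD clustering, backbone turns — but it is NOT a physical
model of CTD phase separation; interactions are square wells between
per-residue sites in units of kT.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .contacts import ContactKey, ContactTable
from .ensemble import ConformerEnsemble, ObservableSet, radius_of_gyration
from .model import (
    Atom,
    Chain,
    Frame,
    Residue,
    Topology,
    Trajectory,
    ValidationError,
    AA_ONE_TO_THREE,
)
from .sequence import parse_sequence

__all__ = [
    "HeptadVariant",
    "generate_heptad_sequence",
    "build_chain",
    "PairPotential",
    "SyntheticSystemSpec",
    "mc_sample_system",
    "FixtureSpec",
    "FixtureFrame",
    "make_contact_fixture",
    "synth_observables",
    "random_conformer_ensemble",
]

HeptadVariant = Literal[
    "WT", "Y1F", "Y1L", "Y1S_odd", "Y1S_nhalf", "Y1S_chalf", "TPPS", "PYP"
]

_WT = "YSPTSPS"


def generate_heptad_sequence(n_repeats: int, variant: HeptadVariant = "WT") -> str:
    """Heptad-repeat sequence for the consensus and its studied variants.

    Tyr-substitution variants replace the position-1 tyrosine: in every
    repeat (Y1F, Y1L), in odd repeats (Y1S_odd), or in the N-/C-terminal
    half of the repeats (Y1S_nhalf / Y1S_chalf).  TPPS and PYP are the
    permuted heptads YSTPPSS and YPSTSSP.
    """
    if n_repeats < 1:
        raise ValidationError("n_repeats must be >= 1")
    if variant == "WT":
        return _WT * n_repeats
    if variant == "TPPS":
        return "YSTPPSS" * n_repeats
    if variant == "PYP":
        return "YPSTSSP" * n_repeats
    if variant in ("Y1F", "Y1L"):
        sub = variant[2]
        return (sub + _WT[1:]) * n_repeats
    if variant in ("Y1S_odd", "Y1S_nhalf", "Y1S_chalf"):
        repeats = []
        n_half = -(-n_repeats // 2)  # ceil
        for k in range(1, n_repeats + 1):
            if variant == "Y1S_odd":
                replace = k % 2 == 1
            elif variant == "Y1S_nhalf":
                replace = k <= n_half
            else:
                replace = k > n_half
            repeats.append(("S" + _WT[1:]) if replace else _WT)
        return "".join(repeats)
    raise ValidationError(f"unknown heptad variant {variant!r}")


# ---------------------------------------------------------------------------
# coarse chain builder

_CA_SPACING = 3.8
_CLASH_DIST = 4.0


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _local_frame(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.array([0.0, 0.0, 1.0])
    if abs(u @ ref) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    n1 = _unit(np.cross(u, ref))
    n2 = np.cross(u, n1)
    return n1, n2


def _residue_atoms(name1: str) -> list[str]:
    backbone = ["N", "CA", "C", "O"]
    if name1 == "G":
        return backbone
    if name1 == "P":
        return backbone + ["CB", "CG", "CD"]
    if name1 == "Y":
        return backbone + ["CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"]
    return backbone + ["CB"]


def _place_residue(
    name1: str,
    ca: np.ndarray,
    u: np.ndarray,
    u_prev: np.ndarray,
    side_sign: float,
) -> list[np.ndarray]:
    n1, n2 = _local_frame(u)
    m = side_sign * n2
    coords = [ca - 1.46 * u_prev, ca, ca + 1.52 * u, ca + 1.52 * u + 1.23 * n1]
    if name1 == "G":
        return coords
    cb = ca + 1.53 * m
    if name1 == "P":
        # pseudo ring closing back toward the backbone nitrogen
        cg = ca + 2.35 * m + 0.4 * u
        cd = coords[0] + 1.47 * m
        return coords + [cb, cg, cd]
    if name1 == "Y":
        rc = cb + 2.1 * m  # pseudo-ring center
        hexagon = [
            rc - 1.39 * m,                     # CG
            rc - 0.695 * m + 1.204 * n1,       # CD1
            rc - 0.695 * m - 1.204 * n1,       # CD2
            rc + 0.695 * m + 1.204 * n1,       # CE1
            rc + 0.695 * m - 1.204 * n1,       # CE2
            rc + 1.39 * m,                     # CZ
        ]
        oh = rc + 1.39 * m + 1.38 * m
        return coords + [cb] + hexagon + [oh]
    return coords + [cb]


def build_chain(
    sequence: str,
    seed: int = 0,
    geometry: Literal["saw", "extended"] = "saw",
    chain_id: str = "A",
    max_restarts: int = 40,
) -> tuple[Chain, np.ndarray]:
    """Build one coarse pseudo-atom conformer; deterministic per seed.

    ``saw`` grows a persistent self-avoiding CA walk (3.8 Å steps, clash
    radius 4 Å on non-adjacent CAs); ``extended`` lays the chain out
    straight, which keeps every O(i)–N(i+3) distance well above 5 Å.
    """
    sequence = parse_sequence(sequence)
    rng = np.random.default_rng(seed)
    n = len(sequence)

    for _ in range(max_restarts):
        if geometry == "extended":
            ca = np.arange(n)[:, None] * np.array([_CA_SPACING, 0.0, 0.0])
            break
        ca = np.zeros((n, 3))
        u = _unit(rng.normal(size=3))
        ok = True
        for i in range(1, n):
            placed = False
            for _attempt in range(60):
                step = _unit(0.9 * u + rng.normal(size=3))
                cand = ca[i - 1] + _CA_SPACING * step
                if i < 2 or np.min(np.linalg.norm(ca[: i - 1] - cand, axis=1)) >= _CLASH_DIST:
                    ca[i] = cand
                    u = step
                    placed = True
                    break
            if not placed:
                ok = False
                break
        if ok:
            break
    else:
        raise ValidationError("self-avoiding walk failed after restart budget")

    residues: list[Residue] = []
    coords: list[np.ndarray] = []
    x_axis = np.array([1.0, 0.0, 0.0])
    for i, letter in enumerate(sequence):
        if n == 1:
            u = x_axis
        else:
            u = _unit(ca[i + 1] - ca[i]) if i < n - 1 else _unit(ca[i] - ca[i - 1])
        u_prev = _unit(ca[i] - ca[i - 1]) if i > 0 and n > 1 else u
        side_sign = 1.0 if geometry == "extended" else float(rng.choice([-1.0, 1.0]))
        names = _residue_atoms(letter)
        pos = _place_residue(letter, ca[i], u, u_prev, side_sign)
        residues.append(
            Residue(index=i + 1, name3=AA_ONE_TO_THREE[letter],
                    atoms=[Atom(name=nm) for nm in names])
        )
        coords.extend(pos)
    return Chain(chain_id=chain_id, residues=residues), np.asarray(coords)


# ---------------------------------------------------------------------------
# Monte-Carlo multi-copy sampler


@dataclass
class PairPotential:
    """Square-well potential between per-residue interaction sites.

    ``depths`` maps unordered label pairs (residue one-letter types by
    default) to well depths in kT; absent pairs do not attract.  All site
    pairs share the hard-core radius and well range.
    """

    depths: dict[frozenset, float] = field(default_factory=dict)
    well_range_A: float = 5.5
    hard_core_A: float = 3.0

    def __post_init__(self):
        if not self.well_range_A > self.hard_core_A > 0:
            raise ValidationError("require well_range > hard_core > 0")
        for pair, depth in self.depths.items():
            if depth < 0:
                raise ValidationError(f"well depth for {set(pair)} must be >= 0")

    @classmethod
    def from_pairs(cls, pairs: dict[tuple[str, str], float], **kw) -> "PairPotential":
        return cls(depths={frozenset(p): d for p, d in pairs.items()}, **kw)

    def depth(self, a: str, b: str) -> float:
        return self.depths.get(frozenset((a, b)), 0.0)


@dataclass
class SyntheticSystemSpec:
    """Study conditions for one multi-copy Monte-Carlo system."""

    sequence: str
    n_copies: int = 4
    box_edge_A: float = 70.0
    n_sweeps: int = 1400
    n_equil_sweeps: int = 400
    sample_stride: int = 20
    temperature_factor: float = 1.0
    seed: int = 0
    sequences: Optional[list[str]] = None  # per-copy override

    def copy_sequences(self) -> list[str]:
        if self.sequences is not None:
            if len(self.sequences) != self.n_copies:
                raise ValidationError("sequences override must match n_copies")
            return [parse_sequence(s) for s in self.sequences]
        return [parse_sequence(self.sequence)] * self.n_copies

    def __post_init__(self):
        if self.n_copies < 1:
            raise ValidationError("n_copies must be >= 1")
        if self.box_edge_A <= 0:
            raise ValidationError("box edge must be positive")
        if self.temperature_factor <= 0:
            raise ValidationError("temperature_factor must be positive")


class _MCState:
    def __init__(self, spec: SyntheticSystemSpec, potential: PairPotential,
                 labels: Optional[Sequence[str]]):
        self.spec = spec
        self.potential = potential
        rng = np.random.default_rng(spec.seed)
        self.rng = rng
        seqs = spec.copy_sequences()
        box = spec.box_edge_A
        chains: list[Chain] = []
        all_coords: list[np.ndarray] = []
        grid_n = int(np.ceil(spec.n_copies ** (1 / 3)))
        cells = [(i, j, k) for i in range(grid_n) for j in range(grid_n) for k in range(grid_n)]
        for ci, seq in enumerate(seqs):
            chain, xyz = build_chain(
                seq, seed=int(rng.integers(2 ** 31)), chain_id=chr(ord("A") + ci)
            )
            # random orientation, centroid on a lattice for maximal separation
            rot = Rotation.random(rng=rng).as_matrix()
            center = xyz.mean(axis=0)
            xyz = (xyz - center) @ rot.T
            cell = np.asarray(cells[ci], dtype=float)
            xyz += (cell + 0.5) * box / grid_n
            chains.append(chain)
            all_coords.append(xyz)
        self.topology = Topology(chains)
        self.topology.assign_copy_indices()
        self.coords = np.vstack(all_coords)
        if box < 2 * potential.hard_core_A:
            raise ValidationError("box too small for the hard-core radius")
        self.box = np.full(3, box)

        top = self.topology
        self.n_res = top.n_residues
        self.res_chain = top.residue_chain
        self.res_atoms = [top.residue_atom_indices(i) for i in range(self.n_res)]
        # interaction site = CB pseudo-atom (CA for glycine): identical local
        # geometry for every residue type, so the null model is type-blind
        # and a CB-CB contact criterion at the well range coincides exactly
        # with the square-well interaction criterion.
        self.site_atoms = []
        for i in range(self.n_res):
            idx = self.res_atoms[i]
            names = top.atom_names[idx]
            cb = idx[names == "CB"]
            self.site_atoms.append(cb if cb.size else idx[names == "CA"])
        if labels is None:
            self.labels = np.asarray(top.residue_name1, dtype=object)
        else:
            self.labels = np.asarray(list(labels), dtype=object)
            if self.labels.size != self.n_res:
                raise ValidationError("labels must cover every residue")
        uniq = sorted(set(map(str, self.labels)))
        self.depth_matrix = np.zeros((len(uniq), len(uniq)))
        lut = {l: i for i, l in enumerate(uniq)}
        for a in uniq:
            for b in uniq:
                self.depth_matrix[lut[a], lut[b]] = potential.depth(a, b)
        self.label_id = np.array([lut[str(l)] for l in self.labels])
        # flat gather/reduceat layout for vectorized site recomputation
        self._site_flat = np.concatenate(self.site_atoms)
        counts = np.array([sa.size for sa in self.site_atoms])
        self._site_offsets = np.concatenate(([0], np.cumsum(counts)[:-1]))
        self._site_counts = counts[:, None].astype(float)
        self.sites = np.empty((self.n_res, 3))
        self._update_sites(None)
        # same-chain neighbours (|i-j| < 2) are excluded from the potential
        self.chain_res = [np.flatnonzero(self.res_chain == c) for c in range(top.n_chains)]
        self.beta = 1.0 / spec.temperature_factor

    # -- energy ------------------------------------------------------------
    def _pair_energy(self, group: np.ndarray) -> float:
        """Interaction energy between residues in `group` and all others
        (the group is internally rigid during a move, so internal terms cancel)."""
        mask = np.ones(self.n_res, dtype=bool)
        mask[group] = False
        others = np.flatnonzero(mask)
        d2 = np.zeros((group.size, others.size))
        sg = self.sites[group]
        so = self.sites[others]
        for ax in range(3):
            delta = sg[:, ax, None] - so[None, :, ax]
            delta -= self.box[ax] * np.round(delta / self.box[ax])
            d2 += delta * delta
        # mask bonded neighbours on the same chain
        bonded = (self.res_chain[group][:, None] == self.res_chain[others][None, :]) & (
            np.abs(group[:, None] - others[None, :]) < 2
        )
        d2[bonded] = np.inf
        if np.any(d2 < self.potential.hard_core_A ** 2):
            return np.inf
        in_well = d2 <= self.potential.well_range_A ** 2
        if not in_well.any():
            return 0.0
        eps = self.depth_matrix[self.label_id[group][:, None], self.label_id[others][None, :]]
        return float(-(eps * in_well).sum())

    def _update_sites(self, res_ids) -> None:
        # recomputing every site is vectorized and cheaper than per-residue means
        sums = np.add.reduceat(self.coords[self._site_flat], self._site_offsets, axis=0)
        self.sites[:] = sums / self._site_counts

    def _attempt(self, res_ids: np.ndarray, new_atom_coords: np.ndarray,
                 atom_idx: np.ndarray) -> bool:
        e_old = self._pair_energy(res_ids)
        old_atoms = self.coords[atom_idx].copy()
        old_sites = self.sites.copy()
        self.coords[atom_idx] = new_atom_coords
        self._update_sites(res_ids)
        e_new = self._pair_energy(res_ids)
        de = e_new - e_old
        if de <= 0 or (np.isfinite(de) and self.rng.random() < np.exp(-self.beta * de)):
            return True
        self.coords[atom_idx] = old_atoms
        self.sites = old_sites
        return False

    def _chain_atoms(self, c: int) -> np.ndarray:
        return np.flatnonzero(self.topology.atom_chain == c)

    def _wrap_chain(self, c: int) -> None:
        idx = self._chain_atoms(c)
        centroid = self.coords[idx].mean(axis=0)
        shift = self.box * np.floor(centroid / self.box)
        if np.any(shift != 0):
            self.coords[idx] -= shift
            self._update_sites(self.chain_res[c])

    def sweep(self) -> None:
        rng = self.rng
        n_chains = self.topology.n_chains
        for c in range(n_chains):
            idx = self._chain_atoms(c)
            res = self.chain_res[c]
            # rigid translation
            disp = rng.normal(scale=3.0, size=3)
            if self._attempt(res, self.coords[idx] + disp, idx):
                self._wrap_chain(c)
            # rigid rotation about the chain centroid
            idx = self._chain_atoms(c)
            center = self.coords[idx].mean(axis=0)
            rot = Rotation.from_rotvec(rng.normal(scale=0.35, size=3)).as_matrix()
            self._attempt(res, (self.coords[idx] - center) @ rot.T + center, idx)
        # internal moves: pivots and crankshafts
        n_internal = max(1, self.n_res // 10)
        for _ in range(n_internal):
            c = int(rng.integers(n_chains))
            res = self.chain_res[c]
            L = res.size
            if L < 4:
                continue
            if rng.random() < 0.5:  # pivot about a CA
                k = int(rng.integers(1, L - 1))
                moved = res[k + 1:]
                if moved.size == 0:
                    continue
                hinge_atoms = self.res_atoms[res[k]]
                names = self.topology.atom_names[hinge_atoms]
                pivot = self.coords[hinge_atoms[names == "CA"][0]]
                rot = Rotation.from_rotvec(rng.normal(scale=0.45, size=3)).as_matrix()
                atom_idx = np.concatenate([self.res_atoms[r] for r in moved])
                new = (self.coords[atom_idx] - pivot) @ rot.T + pivot
                self._attempt(moved, new, atom_idx)
            else:  # crankshaft between two CAs
                if L < 5:
                    continue
                i = int(rng.integers(0, L - 3))
                j = int(rng.integers(i + 2, min(i + 9, L)))
                moved = res[i + 1: j]
                if moved.size == 0:
                    continue
                def _ca(ri):
                    a = self.res_atoms[ri]
                    return self.coords[a[self.topology.atom_names[a] == "CA"][0]]
                axis_a, axis_b = _ca(res[i]), _ca(res[j])
                axis = axis_b - axis_a
                norm = np.linalg.norm(axis)
                if norm < 1e-9:
                    continue
                angle = rng.normal(scale=0.6)
                rot = Rotation.from_rotvec(axis / norm * angle).as_matrix()
                atom_idx = np.concatenate([self.res_atoms[r] for r in moved])
                new = (self.coords[atom_idx] - axis_a) @ rot.T + axis_a
                self._attempt(moved, new, atom_idx)

    def total_energy(self) -> float:
        d2 = np.zeros((self.n_res, self.n_res))
        for ax in range(3):
            delta = self.sites[:, ax, None] - self.sites[None, :, ax]
            delta -= self.box[ax] * np.round(delta / self.box[ax])
            d2 += delta * delta
        bonded = (self.res_chain[:, None] == self.res_chain[None, :]) & (
            np.abs(np.arange(self.n_res)[:, None] - np.arange(self.n_res)[None, :]) < 2
        )
        d2[bonded] = np.inf
        iu = np.triu_indices(self.n_res, k=1)
        du = d2[iu]
        if np.any(du < self.potential.hard_core_A ** 2):
            return np.inf
        in_well = du <= self.potential.well_range_A ** 2
        eps = self.depth_matrix[self.label_id[iu[0]], self.label_id[iu[1]]]
        return float(-(eps * in_well).sum())


def mc_sample_system(
    spec: SyntheticSystemSpec,
    potential: Optional[PairPotential] = None,
    labels: Optional[Sequence[str]] = None,
) -> Trajectory:
    """Sample a multi-copy system by Metropolis Monte Carlo.

    Moves are rigid chain translations/rotations plus internal pivot and
    crankshaft rotations; energies are square wells between per-residue
    sites (side-chain centroids) keyed by ``labels`` (residue types by
    default).  Frames are recorded every ``sample_stride`` sweeps after
    equilibration, with nominal 1 ns frame times so the stride conventions
    of the contact analysis apply directly.  The returned trajectory
    carries ``energy_trace`` (kT per sampled frame) for equilibration
    checks.  Exactly reproducible from (spec, seed).
    """
    potential = potential or PairPotential()
    state = _MCState(spec, potential, labels)
    frames: list[Frame] = []
    energies: list[float] = []
    for sweep in range(spec.n_sweeps):
        state.sweep()
        if sweep >= spec.n_equil_sweeps and (sweep - spec.n_equil_sweeps) % spec.sample_stride == 0:
            frames.append(
                Frame(coords=state.coords.copy(), box=state.box.copy(),
                      time_ps=len(frames) * 1000.0)
            )
            energies.append(state.total_energy())
    if not frames:
        raise ValidationError("no frames sampled; check n_sweeps/equil/stride")
    traj = Trajectory(state.topology, frames)
    traj.energy_trace = np.asarray(energies)
    return traj


# ---------------------------------------------------------------------------
# exact-count contact fixtures


@dataclass
class FixtureFrame:
    """Explicit per-frame coordinates (one CA pseudo-atom per residue) and
    the intended contact set as ((chain, res), (chain, res)) pairs."""

    coords: np.ndarray
    contacts: list[tuple[tuple[str, int], tuple[str, int]]]


@dataclass
class FixtureSpec:
    chain_ids: list[str]
    sequences: list[str]
    frames: list[FixtureFrame]
    cutoff_A: float = 3.5
    box_edge_A: Optional[float] = None
    scope: Literal["intra", "inter"] = "inter"
    min_seq_sep: int = 2


def make_contact_fixture(spec: FixtureSpec) -> tuple[Trajectory, ContactTable]:
    """Build a trajectory realizing exactly the declared contacts.

    The declared contact sets are verified against brute-force distances
    at the declared cutoff (minimum-image when a box is present); an
    inconsistent spec raises instead of returning a broken oracle.
    """
    chains = []
    for cid, seq in zip(spec.chain_ids, spec.sequences):
        seq = parse_sequence(seq)
        chains.append(
            Chain(chain_id=cid, residues=[
                Residue(index=i + 1, name3=AA_ONE_TO_THREE[c], atoms=[Atom(name="CA")])
                for i, c in enumerate(seq)
            ])
        )
    top = Topology(chains)
    top.assign_copy_indices()
    box = None if spec.box_edge_A is None else np.full(3, spec.box_edge_A)

    frames = []
    counts: dict[ContactKey, int] = {}
    per_frame = []
    for t, ff in enumerate(spec.frames):
        coords = np.asarray(ff.coords, dtype=float)
        if coords.shape != (top.n_atoms, 3):
            raise ValidationError("fixture frame has wrong number of residues")
        declared = {ContactKey.make(a[0], a[1], b[0], b[1]) for a, b in ff.contacts}
        # brute-force verification of the declaration
        actual: set[ContactKey] = set()
        for i in range(top.n_residues):
            for j in range(i + 1, top.n_residues):
                ci, cj = top.residue_chain[i], top.residue_chain[j]
                if spec.scope == "inter" and ci == cj:
                    continue
                if spec.scope == "intra" and (
                    ci != cj
                    or abs(top.residue_index[i] - top.residue_index[j]) < spec.min_seq_sep
                ):
                    continue
                d = coords[i] - coords[j]
                if box is not None:
                    best = np.inf
                    for sx in (-1, 0, 1):
                        for sy in (-1, 0, 1):
                            for sz in (-1, 0, 1):
                                img = d + box * np.array([sx, sy, sz])
                                best = min(best, float(np.linalg.norm(img)))
                    dist = best
                else:
                    dist = float(np.linalg.norm(d))
                if dist <= spec.cutoff_A:
                    actual.add(ContactKey.make(
                        chains[ci].chain_id, int(top.residue_index[i]),
                        chains[cj].chain_id, int(top.residue_index[j])))
        if actual != declared:
            raise ValidationError(
                f"fixture frame {t}: declared contacts {sorted(declared)} do not "
                f"match geometry {sorted(actual)}"
            )
        frames.append(Frame(coords=coords, box=box, time_ps=t * 1000.0))
        per_frame.append(frozenset(declared))
        for key in declared:
            counts[key] = counts.get(key, 0) + 1
    traj = Trajectory(top, frames)
    table = ContactTable(
        scope=spec.scope,
        window_start_ps=0.0,
        window_end_ps=(len(frames) - 1) * 1000.0,
        stride_ps=1000.0,
        n_frames_analyzed=len(frames),
        counts=counts,
        per_frame=per_frame,
    )
    return traj, table


# ---------------------------------------------------------------------------
# synthetic observables


def random_conformer_ensemble(
    sequence: str, n_conformers: int, seed: int = 0
) -> ConformerEnsemble:
    """Independent self-avoiding-walk conformers sharing one topology."""
    rng = np.random.default_rng(seed)
    chain0, coords0 = build_chain(sequence, seed=int(rng.integers(2 ** 31)))
    top = Topology([chain0])
    frames = [Frame(coords=coords0, time_ps=0.0)]
    for k in range(1, n_conformers):
        _, xyz = build_chain(sequence, seed=int(rng.integers(2 ** 31)))
        frames.append(Frame(coords=xyz, time_ps=float(k)))
    return ConformerEnsemble(Trajectory(top, frames))


def synth_observables(
    ensemble: ConformerEnsemble,
    true_weights: np.ndarray,
    noise_sd: float,
    seed: int = 0,
    n_distances: int = 5,
    sigma: Optional[float] = None,
) -> ObservableSet:
    """Structure-derived observables with ground-truth ensemble averages.

    Per conformer: the radius of gyration plus ``n_distances`` seeded
    CA–CA distances.  Experimental values are the true-weight averages
    plus Gaussian noise of scale ``noise_sd``; the σ column equals
    ``noise_sd`` unless a nominal ``sigma`` is given (required for the
    noise-free case ``noise_sd = 0``).
    """
    if sigma is None:
        sigma = noise_sd
    if sigma <= 0:
        raise ValidationError("σ must be positive: set noise_sd > 0 or pass sigma")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be non-negative")
    w = np.asarray(true_weights, dtype=float)
    traj = ensemble.trajectory
    if w.shape != (traj.n_frames,) or np.any(w < 0) or not np.isclose(w.sum(), 1.0):
        raise ValidationError("true_weights must be a distribution over conformers")
    rng = np.random.default_rng(seed)
    top = traj.topology
    ca_idx = np.flatnonzero(top.atom_names == "CA")
    pairs = []
    names = ["Rg"]
    for _ in range(n_distances):
        i, j = rng.choice(ca_idx.size, size=2, replace=False)
        pairs.append((ca_idx[i], ca_idx[j]))
        names.append(f"d_CA{i + 1}_CA{j + 1}")
    predicted = np.empty((traj.n_frames, 1 + n_distances))
    for k, frame in enumerate(traj.frames):
        predicted[k, 0] = radius_of_gyration(frame)
        for c, (ia, ib) in enumerate(pairs):
            predicted[k, c + 1] = np.linalg.norm(frame.coords[ia] - frame.coords[ib])
    experimental = w @ predicted
    if noise_sd > 0:
        experimental = experimental + rng.normal(scale=noise_sd, size=1 + n_distances)
    return ObservableSet(predicted=predicted, experimental=experimental,
                         sigma=np.full(1 + n_distances, sigma), names=names)
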