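"""Core structural data model: atoms, residues, chains, topology, frames, trajectories.

Internal length unit is the angstrom throughout the package; configuration
surfaces accept nanometres where the literature quotes them and convert
exactly (1 nm = 10 Å).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "Topology",
    "Frame",
    "Trajectory",
    "ValidationError",
    "StructuralInconsistencyError",
    "AA_THREE_TO_ONE",
    "AA_ONE_TO_THREE",
    "KYTE_DOOLITTLE",
    "element_from_name",
]


class ValidationError(ValueError):
    """Raised when inputs violate a documented precondition."""


class StructuralInconsistencyError(ValueError):
    """Raised when models of a multi-model file disagree structurally."""


AA_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA_ONE_TO_THREE = {v: k for k, v in AA_THREE_TO_ONE.items()}

# Kyte & Doolittle hydropathy scale (dimensionless per-residue values).
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}


def element_from_name(name: str) -> str:
    """Infer the element symbol from a standard amino-acid atom name.

    PDB convention: a leading digit marks a hydrogen variant (e.g. ``1HB``);
    otherwise the first alphabetic character is the element for C/N/O/S/H
    atoms of the 20 standard residues.
    """
    stripped = name.strip()
    if not stripped:
        raise ValidationError("empty atom name")
    for ch in stripped:
        if ch.isalpha():
            return ch.upper()
    raise ValidationError(f"cannot infer element from atom name {name!r}")


@dataclass(frozen=True)
class Atom:
    name: str
    element: str = ""

    def __post_init__(self):
        if not self.element:
            object.__setattr__(self, "element", element_from_name(self.name))

    @property
    def is_heavy(self) -> bool:
        return self.element != "H"


@dataclass
class Residue:
    """One residue: 1-based ``index`` within its chain, three-letter code, atoms."""

    index: int
    name3: str
    atoms: list[Atom] = field(default_factory=list)

    def __post_init__(self):
        names = [a.name for a in self.atoms]
        if len(names) != len(set(names)):
            raise ValidationError(
                f"duplicate atom names in residue {self.name3}{self.index}"
            )

    @property
    def name1(self) -> str:
        return AA_THREE_TO_ONE.get(self.name3, "X")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)
    copy_index: int = 0

    def __post_init__(self):
        idx = [r.index for r in self.residues]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValidationError(
                f"residue indices in chain {self.chain_id} must strictly increase"
            )

    @property
    def sequence(self) -> str:
        return "".join(r.name1 for r in self.residues)

    @property
    def n_atoms(self) -> int:
        return sum(r.n_atoms for r in self.residues)


class Topology:
    """Ordered chains; provides flat per-atom index arrays for vector math."""

    def __init__(self, chains: Sequence[Chain]):
        self.chains: list[Chain] = list(chains)
        ids = [c.chain_id for c in self.chains]
        if len(ids) != len(set(ids)):
            raise ValidationError("chain_id values must be unique")
        self._build_index()

    def _build_index(self) -> None:
        atom_chain, atom_res, atom_name, atom_heavy = [], [], [], []
        res_chain, res_index, res_name1 = [], [], []
        self._res_atom_start: list[int] = []
        offset = 0
        for ci, chain in enumerate(self.chains):
            for res in chain.residues:
                self._res_atom_start.append(offset)
                res_chain.append(ci)
                res_index.append(res.index)
                res_name1.append(res.name1)
                for atom in res.atoms:
                    atom_chain.append(ci)
                    atom_res.append(len(res_chain) - 1)
                    atom_name.append(atom.name)
                    atom_heavy.append(atom.is_heavy)
                offset += res.n_atoms
        self.n_atoms = offset
        self.n_residues = len(res_chain)
        self.atom_chain = np.asarray(atom_chain, dtype=np.int32)
        self.atom_residue = np.asarray(atom_res, dtype=np.int32)
        self.atom_names = np.asarray(atom_name, dtype=object)
        self.atom_is_heavy = np.asarray(atom_heavy, dtype=bool)
        self.residue_chain = np.asarray(res_chain, dtype=np.int32)
        self.residue_index = np.asarray(res_index, dtype=np.int32)
        self.residue_name1 = np.asarray(res_name1, dtype=object)

    @property
    def n_chains(self) -> int:
        return len(self.chains)

    def residue(self, chain_id: str, index: int) -> Residue:
        chain = self.chain(chain_id)
        for res in chain.residues:
            if res.index == index:
                return res
        raise ValidationError(f"residue {index} not found in chain {chain_id}")

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise ValidationError(f"chain {chain_id!r} not in topology")

    def flat_residue_id(self, chain_id: str, index: int) -> int:
        """Global 0-based residue ordinal for a (chain, residue-index) pair."""
        for ci, c in enumerate(self.chains):
            if c.chain_id == chain_id:
                hits = np.flatnonzero(
                    (self.residue_chain == ci) & (self.residue_index == index)
                )
                if hits.size == 0:
                    raise ValidationError(
                        f"residue {index} not found in chain {chain_id}"
                    )
                return int(hits[0])
        raise ValidationError(f"chain {chain_id!r} not in topology")

    def residue_atom_indices(self, flat_res_id: int, heavy_only: bool = False) -> np.ndarray:
        sel = np.flatnonzero(self.atom_residue == flat_res_id)
        if heavy_only:
            sel = sel[self.atom_is_heavy[sel]]
        return sel

    def assign_copy_indices(self) -> None:
        """Chains with identical residue sequences are copies of one species;
        copy_index counts them in file order."""
        seen: dict[str, int] = {}
        for chain in self.chains:
            seq = chain.sequence
            chain.copy_index = seen.get(seq, 0)
            seen[seq] = chain.copy_index + 1

    def single_species(self) -> bool:
        seqs = {c.sequence for c in self.chains}
        return len(seqs) == 1


@dataclass
class Frame:
    """One coordinate snapshot: Å positions, optional orthorhombic box edges (Å)."""

    coords: np.ndarray
    box: Optional[np.ndarray] = None
    time_ps: float = 0.0

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValidationError("coords must be an (n_atoms, 3) array")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float).reshape(3)
            if np.any(self.box <= 0):
                raise ValidationError("box edges must be positive")


class Trajectory:
    def __init__(self, topology: Topology, frames: Sequence[Frame]):
        self.topology = topology
        self.frames: list[Frame] = list(frames)
        for fr in self.frames:
            if fr.coords.shape[0] != topology.n_atoms:
                raise StructuralInconsistencyError(
                    f"frame has {fr.coords.shape[0]} atoms, topology has "
                    f"{topology.n_atoms}"
                )
        times = [fr.time_ps for fr in self.frames]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValidationError("frame times must be non-decreasing")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[Frame]:
        return iter(self.frames)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def times_ps(self) -> np.ndarray:
        return np.asarray([fr.time_ps for fr in self.frames], dtype=float)
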