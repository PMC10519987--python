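"""Multi-model PDB reading/writing and the trajectory-adapter registry.

The mandatory on-disk format is multi-model PDB (MODEL/ENDMDL records,
CRYST1 for the orthorhombic box).  Binary trajectory formats plug in
through :func:`register_adapter`: an adapter is any callable
``(path) -> Trajectory`` that yields a full topology and frames carrying
``time_ps``.

PDB has no native time record, so frame times are stored in
``REMARK   6 TIME_PS <model> <ps>`` lines and recovered on read; files
without them get times ``0, 1000, 2000, ...`` ps (the 1 ns analysis grid).
Water and ion records are dropped on read with a logged count.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Callable

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .model import (
    Atom,
    Chain,
    Frame,
    Residue,
    StructuralInconsistencyError,
    Topology,
    Trajectory,
    ValidationError,
)

__all__ = ["read_trajectory", "write_trajectory", "register_adapter", "list_adapters"]

logger = logging.getLogger(__name__)

SOLVENT_RES_NAMES = {
    "HOH", "WAT", "SOL", "TIP3", "TIP4", "T4P", "T3P",
    "NA", "CL", "SOD", "CLA", "K", "MG", "ZN", "CS", "LI", "BR", "IOD",
}

_TIME_REMARK = "REMARK   6 TIME_PS"

_ADAPTERS: dict[str, Callable[[str], Trajectory]] = {}


def register_adapter(name: str, reader: Callable[[str], Trajectory]) -> None:
    """Register a trajectory reader under a format name."""
    _ADAPTERS[name] = reader


def list_adapters() -> list[str]:
    return sorted(_ADAPTERS) + ["multi-model-pdb"]


def _check_model_consistency(path: str) -> None:
    """Models must contain identical atom counts; report the offender."""
    counts: list[int] = []
    current = 0
    in_model = False
    with open(path) as fh:
        for line in fh:
            rec = line[:6].strip()
            if rec == "MODEL":
                in_model = True
                current = 0
            elif rec == "ENDMDL":
                counts.append(current)
                in_model = False
            elif rec in ("ATOM", "HETATM") and in_model:
                current += 1
    if counts and len(set(counts)) > 1:
        raise StructuralInconsistencyError(
            f"{path}: models have inconsistent atom counts {sorted(set(counts))}"
        )


def _parse_time_remarks(pdb_file: PDBFile) -> dict[int, float]:
    times: dict[int, float] = {}
    for line in pdb_file.lines:
        if line.startswith(_TIME_REMARK):
            parts = line.split()
            # REMARK 6 TIME_PS <model> <ps>
            try:
                times[int(parts[3])] = float(parts[4])
            except (IndexError, ValueError):
                continue
    return times


def read_trajectory(path: str, format: str = "multi-model-pdb") -> Trajectory:
    """Read a trajectory file into the package's data model.

    Chains whose residue sequences are identical are treated as copies of
    one molecular species and receive consecutive ``copy_index`` values in
    file order.
    """
    path = str(path)
    if not Path(path).exists():
        raise FileNotFoundError(path)
    if format in _ADAPTERS:
        return _ADAPTERS[format](path)
    if format not in ("multi-model-pdb", "pdb"):
        raise ValidationError(f"unsupported trajectory format {format!r}")

    _check_model_consistency(path)
    try:
        pdb_file = PDBFile.read(path)
        stack = pdb_file.get_structure(model=None)
    except StructuralInconsistencyError:
        raise
    except Exception as exc:  # biotite raises various parse errors
        raise ValidationError(f"failed to parse PDB file {path}: {exc}") from exc

    solvent_mask = np.isin(stack.res_name, sorted(SOLVENT_RES_NAMES))
    n_dropped = int(solvent_mask.sum())
    if n_dropped:
        logger.info("dropped %d solvent/ion atoms while reading %s", n_dropped, path)
        stack = stack[..., ~solvent_mask]
    if stack.array_length() == 0:
        raise ValidationError(f"{path}: no protein atoms after solvent removal")

    chains: list[Chain] = []
    chain_ids = stack.chain_id
    res_ids = stack.res_id
    res_names = stack.res_name
    atom_names = stack.atom_name
    elements = stack.element
    # preserve file order of chains
    order: list[str] = []
    for cid in chain_ids:
        if cid not in order:
            order.append(cid)
    for cid in order:
        cmask = chain_ids == cid
        residues: list[Residue] = []
        seen: list[int] = []
        for rid in res_ids[cmask]:
            if not seen or rid != seen[-1]:
                seen.append(int(rid))
        for rid in seen:
            rmask = cmask & (res_ids == rid)
            atoms = [
                Atom(name=str(an), element=str(el).upper() or "")
                for an, el in zip(atom_names[rmask], elements[rmask])
            ]
            residues.append(Residue(index=rid, name3=str(res_names[rmask][0]), atoms=atoms))
        chains.append(Chain(chain_id=str(cid), residues=residues))

    topology = Topology(chains)
    topology.assign_copy_indices()

    # reorder coordinate columns to the topology's atom order
    atom_order = []
    for cid in order:
        sel = np.flatnonzero(chain_ids == cid)
        atom_order.extend(sel.tolist())
    atom_order = np.asarray(atom_order, dtype=int)

    box_edges = None
    if stack.box is not None:
        box_edges = np.diagonal(np.asarray(stack.box), axis1=-2, axis2=-1)

    times = _parse_time_remarks(pdb_file)
    frames = []
    for m in range(stack.stack_depth()):
        box = None
        if box_edges is not None and np.all(box_edges[m] > 0):
            box = box_edges[m]
        frames.append(
            Frame(
                coords=stack.coord[m][atom_order],
                box=box,
                time_ps=times.get(m + 1, m * 1000.0),
            )
        )
    return Trajectory(topology, frames)


def write_trajectory(trajectory: Trajectory, path: str, format: str = "multi-model-pdb") -> None:
    """Write a trajectory as multi-model PDB (readable back by read_trajectory)."""
    if format not in ("multi-model-pdb", "pdb"):
        raise ValidationError(f"unsupported output format {format!r}")
    if trajectory.n_frames == 0:
        raise ValidationError("cannot write a trajectory with no frames")
    top = trajectory.topology
    n = top.n_atoms
    m = trajectory.n_frames

    stack = struc.AtomArrayStack(m, n)
    chain_id = np.empty(n, dtype="U4")
    res_id = np.empty(n, dtype=int)
    res_name = np.empty(n, dtype="U5")
    atom_name = np.empty(n, dtype="U6")
    element = np.empty(n, dtype="U2")
    i = 0
    for chain in top.chains:
        for res in chain.residues:
            for atom in res.atoms:
                chain_id[i] = chain.chain_id
                res_id[i] = res.index
                res_name[i] = res.name3
                atom_name[i] = atom.name
                element[i] = atom.element
                i += 1
    stack.chain_id = chain_id
    stack.res_id = res_id
    stack.res_name = res_name
    stack.atom_name = atom_name
    stack.element = element
    stack.hetero = np.zeros(n, dtype=bool)
    stack.coord = np.stack([fr.coords for fr in trajectory.frames])

    boxes = [fr.box for fr in trajectory.frames]
    if any(b is not None for b in boxes):
        if any(b is None for b in boxes):
            raise ValidationError("either all frames or no frames may carry a box")
        stack.box = np.stack([np.diag(b) for b in boxes])

    pdb_file = PDBFile()
    pdb_file.set_structure(stack)
    remarks = [
        f"{_TIME_REMARK} {k + 1} {fr.time_ps:.3f}"
        for k, fr in enumerate(trajectory.frames)
    ]
    pdb_file.lines = remarks + pdb_file.lines
    try:
        pdb_file.write(str(path))
    except OSError as exc:
        raise OSError(f"cannot write trajectory to {path}: {exc}") from exc
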