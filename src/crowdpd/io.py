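"""Trajectory and restart I/O.

Snapshots are written as extended XYZ: a bead count, a comment line carrying
the box (``Lattice=...``), the column layout (``Properties=...``) and the
step index, then one line per bead with its type label, position and
velocity.  Positions and velocities are printed with 17 significant digits,
so a written snapshot reloads bit-exactly and serves as a restart file.

The topology (molecule membership, bonds, angles) is constant over a run
and lives in a JSON sidecar written once per trajectory.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, TextIO

import numpy as np

from .builder import SOLVENT_ID, State
from .model import BEAD_INDEX, BEAD_TYPES

__all__ = [
    "write_xyz",
    "read_xyz",
    "write_topology",
    "read_topology",
    "save_state",
    "load_state",
]

_FMT = "%.17g"


def write_xyz(path_or_file: str | Path | TextIO, state: State, append: bool = False) -> None:
    """Write one extended-XYZ frame (type label, position, velocity)."""
    if hasattr(path_or_file, "write"):
        _write_frame(path_or_file, state)
        return
    mode = "a" if append else "w"
    with open(path_or_file, mode) as fh:
        _write_frame(fh, state)


def _write_frame(fh: TextIO, state: State) -> None:
    box = state.box
    fh.write(f"{state.n_beads}\n")
    lattice = (
        f"{_FMT % box[0]} 0 0 0 {_FMT % box[1]} 0 0 0 {_FMT % box[2]}"
    )
    fh.write(
        f'Lattice="{lattice}" '
        "Properties=species:S:1:pos:R:3:vel:R:3 "
        f"step={state.step}\n"
    )
    labels = [BEAD_TYPES[t] for t in state.bead_types]
    pos = state.positions
    vel = state.velocities
    for i in range(state.n_beads):
        fh.write(
            f"{labels[i]} "
            f"{_FMT % pos[i, 0]} {_FMT % pos[i, 1]} {_FMT % pos[i, 2]} "
            f"{_FMT % vel[i, 0]} {_FMT % vel[i, 1]} {_FMT % vel[i, 2]}\n"
        )


def read_xyz(path: str | Path, frame: int = 0) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, int]:
    """Read one frame; returns (positions, velocities, type codes, box, step).

    ``frame`` selects a frame in a multi-frame trajectory; negative indices
    count from the end.
    """
    frames = []
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            n = int(header)
            comment = fh.readline()
            lines = [fh.readline() for _ in range(n)]
            frames.append((comment, lines))
    if not frames:
        raise ValueError(f"no frames in {path}")
    comment, lines = frames[frame]

    box = np.array([48.0, 48.0, 48.0])
    step = 0
    if 'Lattice="' in comment:
        lattice = comment.split('Lattice="')[1].split('"')[0].split()
        box = np.array([float(lattice[0]), float(lattice[4]), float(lattice[8])])
    for token in comment.split():
        if token.startswith("step="):
            step = int(token[5:])

    n = len(lines)
    pos = np.empty((n, 3))
    vel = np.zeros((n, 3))
    types = np.empty(n, dtype=np.int64)
    for i, line in enumerate(lines):
        parts = line.split()
        types[i] = BEAD_INDEX[parts[0]]
        pos[i] = [float(x) for x in parts[1:4]]
        if len(parts) >= 7:
            vel[i] = [float(x) for x in parts[4:7]]
    return pos, vel, types, box, step


def write_topology(path: str | Path, state: State) -> None:
    """Write the constant per-run topology sidecar (JSON)."""
    data = {
        "molecule_ids": state.molecule_ids.tolist(),
        "bonds": state.bonds.tolist(),
        "angles": state.angles.tolist(),
        "solvent_id": SOLVENT_ID,
    }
    Path(path).write_text(json.dumps(data))


def read_topology(path: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read a topology sidecar; returns (molecule_ids, bonds, angles)."""
    data = json.loads(Path(path).read_text())
    return (
        np.asarray(data["molecule_ids"], dtype=np.int64),
        np.asarray(data["bonds"], dtype=np.int64).reshape(-1, 2),
        np.asarray(data["angles"], dtype=np.int64).reshape(-1, 3),
    )


def save_state(prefix: str | Path, state: State) -> tuple[Path, Path]:
    """Write ``<prefix>.xyz`` and ``<prefix>.topology.json`` for a restart."""
    prefix = Path(prefix)
    xyz = prefix.with_suffix(".xyz")
    topo = prefix.with_suffix(".topology.json")
    write_xyz(xyz, state)
    write_topology(topo, state)
    return xyz, topo


def load_state(prefix: str | Path, frame: int = 0) -> State:
    """Reconstruct a State written by :func:`save_state` (bit-exact)."""
    prefix = Path(prefix)
    pos, vel, types, box, step = read_xyz(prefix.with_suffix(".xyz"), frame=frame)
    mol_ids, bonds, angles = read_topology(prefix.with_suffix(".topology.json"))
    if mol_ids.shape[0] != pos.shape[0]:
        raise ValueError("topology does not match the snapshot bead count")
    return State(
        positions=pos,
        velocities=vel,
        bead_types=types,
        molecule_ids=mol_ids,
        bonds=bonds,
        angles=angles,
        box=box,
        step=step,
    )
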