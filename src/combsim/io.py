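"""Trajectory, checkpoint and report file handling.

Two plain-text trajectory dialects are supported so snapshots are readable
by standard molecular viewers and by MDAnalysis:

* XYZ: per frame "natoms / comment / SYMBOL x y z ...".  The comment line
  carries ``step=<int> box=<Lx>,<Ly>,<Lz>`` so a round trip restores the
  periodic cell.
* LAMMPS dump: ITEM: TIMESTEP / NUMBER OF ATOMS / BOX BOUNDS pp pp pp /
  ATOMS id type xs ys zs (scaled coordinates).

Coordinates are written wrapped into the primary box by default.  Full
simulation state (including unwrapped positions, bonds, chain ids and the
step counter) goes to HDF5 checkpoints for exact restarts.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .bd import SimulationState, Trajectory

_SYMBOLS = np.array(["A", "B"])


class TrajectoryFormatError(ValueError):
    pass


# ---------------------------------------------------------------------------
# XYZ
# ---------------------------------------------------------------------------

def write_xyz(path, traj: Trajectory, wrapped: bool = True) -> None:
    with open(path, "w") as fh:
        for pos, stepno in zip(traj.frames, traj.steps):
            p = pos
            if wrapped:
                p = p - traj.box * np.floor(p / traj.box)
            fh.write(f"{len(p)}\n")
            bx = ",".join(f"{x:.10g}" for x in traj.box)
            fh.write(f"step={stepno} box={bx}\n")
            for s, (x, y, z) in zip(traj.species, p):
                fh.write(f"{_SYMBOLS[s]} {x:.9f} {y:.9f} {z:.9f}\n")


def read_xyz(path) -> Trajectory:
    frames, steps = [], []
    species = None
    box = None
    with open(path) as fh:
        lines = fh.read().split("\n")
    i = 0
    nframe = 0
    while i < len(lines) and lines[i].strip():
        try:
            n = int(lines[i])
        except ValueError as e:
            raise TrajectoryFormatError(
                f"frame {nframe}: bad atom count line {lines[i]!r}"
            ) from e
        comment = lines[i + 1]
        meta = dict(
            kv.split("=", 1) for kv in comment.split() if "=" in kv
        )
        stepno = int(meta.get("step", nframe))
        if "box" in meta:
            box = np.array([float(x) for x in meta["box"].split(",")])
        elif box is None:
            raise TrajectoryFormatError("no box metadata in XYZ comment line")
        sp = np.empty(n, np.int8)
        pos = np.empty((n, 3))
        for k in range(n):
            parts = lines[i + 2 + k].split()
            if len(parts) < 4:
                raise TrajectoryFormatError(
                    f"frame {nframe}: malformed atom line {i + 2 + k + 1}"
                )
            sp[k] = 0 if parts[0] == "A" else 1
            pos[k] = [float(v) for v in parts[1:4]]
        if species is None:
            species = sp
        frames.append(pos)
        steps.append(stepno)
        i += 2 + n
        nframe += 1
    if not frames:
        raise TrajectoryFormatError(f"{path}: empty trajectory")
    return Trajectory(
        frames=frames, steps=steps, species=species, box=box,
        bonds=np.empty((0, 2), np.int64),
        chain_id=np.zeros(len(species), np.int64),
    )


# ---------------------------------------------------------------------------
# LAMMPS dump (id type xs ys zs)
# ---------------------------------------------------------------------------

def write_lammps_dump(path, traj: Trajectory) -> None:
    with open(path, "w") as fh:
        for pos, stepno in zip(traj.frames, traj.steps):
            w = pos - traj.box * np.floor(pos / traj.box)
            s = w / traj.box
            fh.write("ITEM: TIMESTEP\n%d\n" % stepno)
            fh.write("ITEM: NUMBER OF ATOMS\n%d\n" % len(pos))
            fh.write("ITEM: BOX BOUNDS pp pp pp\n")
            for L in traj.box:
                fh.write(f"0.0 {L:.10g}\n")
            fh.write("ITEM: ATOMS id type xs ys zs\n")
            for k in range(len(pos)):
                fh.write(
                    f"{k + 1} {traj.species[k] + 1} "
                    f"{s[k, 0]:.9f} {s[k, 1]:.9f} {s[k, 2]:.9f}\n"
                )


def read_lammps_dump(path) -> Trajectory:
    frames, steps = [], []
    species = None
    box = None
    with open(path) as fh:
        lines = fh.read().split("\n")
    i = 0
    nframe = 0
    while i < len(lines) and lines[i].startswith("ITEM: TIMESTEP"):
        try:
            stepno = int(lines[i + 1])
            n = int(lines[i + 3])
            box = np.array(
                [float(lines[i + 5 + k].split()[1])
                 - float(lines[i + 5 + k].split()[0]) for k in range(3)]
            )
            header = lines[i + 8].replace("ITEM: ATOMS", "").split()
            cid = {c: j for j, c in enumerate(header)}
            sp = np.empty(n, np.int8)
            pos = np.empty((n, 3))
            for k in range(n):
                parts = lines[i + 9 + k].split()
                idx = int(parts[cid["id"]]) - 1
                sp[idx] = int(parts[cid["type"]]) - 1
                pos[idx] = [
                    float(parts[cid["xs"]]) * box[0],
                    float(parts[cid["ys"]]) * box[1],
                    float(parts[cid["zs"]]) * box[2],
                ]
        except (ValueError, IndexError, KeyError) as e:
            raise TrajectoryFormatError(
                f"frame {nframe}: malformed LAMMPS dump entry"
            ) from e
        if species is None:
            species = sp
        frames.append(pos)
        steps.append(stepno)
        i += 9 + n
        nframe += 1
    if not frames:
        raise TrajectoryFormatError(f"{path}: empty trajectory")
    return Trajectory(
        frames=frames, steps=steps, species=species, box=box,
        bonds=np.empty((0, 2), np.int64),
        chain_id=np.zeros(len(species), np.int64),
    )


# ---------------------------------------------------------------------------
# LAMMPS data (topology export) and bonds/types table
# ---------------------------------------------------------------------------

def write_lammps_data(path, state: SimulationState) -> None:
    """Single-configuration LAMMPS data file (atom_style bond)."""
    w = state.wrapped_positions()
    with open(path, "w") as fh:
        fh.write("comb copolymer system\n\n")
        fh.write(f"{state.n_beads} atoms\n{len(state.bonds)} bonds\n\n")
        fh.write("2 atom types\n1 bond types\n\n")
        for L, ax in zip(state.box, ("x", "y", "z")):
            fh.write(f"0.0 {L:.10g} {ax}lo {ax}hi\n")
        fh.write("\nMasses\n\n1 1.0\n2 1.0\n\nAtoms\n\n")
        for i in range(state.n_beads):
            fh.write(
                f"{i + 1} {state.chain_id[i] + 1} {state.species[i] + 1} "
                f"{w[i, 0]:.9f} {w[i, 1]:.9f} {w[i, 2]:.9f}\n"
            )
        if len(state.bonds):
            fh.write("\nBonds\n\n")
            for b, (i, j) in enumerate(state.bonds):
                fh.write(f"{b + 1} 1 {i + 1} {j + 1}\n")


def write_topology_table(path, state: SimulationState) -> None:
    """Simple text table: bead id, species letter, chain id; then bonds."""
    with open(path, "w") as fh:
        fh.write("# beads: id species chain\n")
        for i in range(state.n_beads):
            fh.write(f"{i} {_SYMBOLS[state.species[i]]} {state.chain_id[i]}\n")
        fh.write("# bonds: i j\n")
        for i, j in state.bonds:
            fh.write(f"{i} {j}\n")


# ---------------------------------------------------------------------------
# HDF5 checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(path, state: SimulationState) -> None:
    with h5py.File(path, "w") as h5:
        h5.create_dataset("positions", data=state.positions)
        h5.create_dataset("species", data=state.species)
        h5.create_dataset("box", data=state.box)
        h5.create_dataset("bonds", data=state.bonds)
        h5.create_dataset("chain_id", data=state.chain_id)
        h5.attrs["step"] = state.step


def load_checkpoint(path) -> SimulationState:
    with h5py.File(path, "r") as h5:
        return SimulationState(
            positions=h5["positions"][...],
            species=h5["species"][...],
            box=h5["box"][...],
            bonds=h5["bonds"][...],
            chain_id=h5["chain_id"][...],
            step=int(h5.attrs["step"]),
        )


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def write_reports_tsv(path, reports, steps=None) -> None:
    """Per-frame morphology reports as a TSV table."""
    import pandas as pd

    rows = []
    for i, r in enumerate(reports):
        rows.append({
            "frame": i,
            "step": steps[i] if steps is not None else i,
            "label": r.label,
            "rg": r.rg,
            "asphericity": r.asphericity,
            "lambda1": r.eigenvalues[0],
            "lambda2": r.eigenvalues[1],
            "lambda3": r.eigenvalues[2],
            "chain_fraction": r.chain_fraction,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_phase_diagram_json(path, entries: dict) -> None:
    """Phase-diagram summary keyed by "x,y,n" strings."""
    Path(path).write_text(json.dumps(entries, indent=2, sort_keys=True) + "\n")


def write_profile_tsv(path, profile) -> None:
    import pandas as pd

    pd.DataFrame({
        "r": profile.centers,
        "density_B": profile.density,
        "density_total": profile.total_density,
        "count_B": profile.counts,
    }).to_csv(path, sep="\t", index=False)


def write_field_grid(path, grid, arrays: dict) -> None:
    """Plain-text dump of SCFT density fields with a shape header."""
    with open(path, "w") as fh:
        fh.write("# shape: " + " ".join(str(s) for s in grid.shape) + "\n")
        fh.write("# columns: " + " ".join(arrays) + "\n")
        flat = [np.asarray(a).ravel() for a in arrays.values()]
        for row in zip(*flat):
            fh.write(" ".join(f"{v:.8g}" for v in row) + "\n")
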