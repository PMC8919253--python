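"""File formats: multi-frame XYZ trajectories, JSON manifests, CSV tables.

The XYZ dialect is the plain ``N / comment / N atom lines`` stack, with the
comment line carrying ``key=value`` metadata (time_fs plus trajectory
provenance) and each atom line carrying element, position (Å) and velocity
(Å/fs) at six decimals.  Positions survive a write→read→write cycle exactly.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from .chem import MolecularGraph
from .simulate import Trajectory


def _format_meta(meta: dict) -> str:
    return " ".join(f"{k}={v}" for k, v in meta.items())


def _parse_meta(comment: str) -> dict:
    out: dict = {}
    for tok in comment.split():
        if "=" not in tok:
            continue
        k, v = tok.split("=", 1)
        for cast in (int, float):
            try:
                out[k] = cast(v)
                break
            except ValueError:
                continue
        else:
            out[k] = v
    return out


def write_xyz(path, traj: Trajectory, elements) -> None:
    """Write a trajectory as multi-frame XYZ.

    ``elements`` is the per-atom element symbol list (from the topology).
    """
    if len(elements) != traj.n_atoms:
        raise ValueError("element list does not match trajectory atom count")
    with open(path, "w") as fh:
        for k in range(traj.n_frames):
            meta = dict(traj.metadata)
            meta["time_fs"] = f"{traj.times_fs[k]:.6f}"
            fh.write(f"{traj.n_atoms}\n")
            fh.write(_format_meta(meta) + "\n")
            for el, p, v in zip(elements, traj.positions[k], traj.velocities[k]):
                fh.write(
                    f"{el} {p[0]:.6f} {p[1]:.6f} {p[2]:.6f} "
                    f"{v[0]:.6f} {v[1]:.6f} {v[2]:.6f}\n"
                )


def read_xyz(path):
    """Read a multi-frame XYZ trajectory.

    Returns (Trajectory, element list).  Raises ValueError naming the frame
    on malformed input or inconsistent atom counts.
    """
    lines = Path(path).read_text().splitlines()
    pos_frames, vel_frames, times, elements = [], [], [], None
    meta: dict = {}
    i, frame_no = 0, 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        frame_no += 1
        try:
            n = int(lines[i].strip())
        except ValueError as err:
            raise ValueError(f"frame {frame_no}: bad atom-count line") from err
        if i + 1 + n >= len(lines) + 1:
            raise ValueError(f"frame {frame_no}: truncated")
        frame_meta = _parse_meta(lines[i + 1])
        t = frame_meta.pop("time_fs", float(len(times)))
        meta = frame_meta or meta
        els, P, V = [], [], []
        for j in range(n):
            parts = lines[i + 2 + j].split()
            if len(parts) not in (4, 7):
                raise ValueError(f"frame {frame_no}: malformed atom line {j + 1}")
            els.append(parts[0])
            P.append([float(x) for x in parts[1:4]])
            V.append([float(x) for x in parts[4:7]] if len(parts) == 7 else [0.0] * 3)
        if elements is None:
            elements = els
        elif els != elements:
            raise ValueError(f"frame {frame_no}: atom list differs from frame 1")
        times.append(float(t))
        pos_frames.append(P)
        vel_frames.append(V)
        i += 2 + n
    if not pos_frames:
        raise ValueError("no frames found")
    traj = Trajectory(
        np.array(times), np.array(pos_frames), np.array(vel_frames), meta
    )
    return traj, elements


def write_single_frame_xyz(path, graph: MolecularGraph, positions) -> None:
    """One-frame XYZ of a topology + coordinate set (e.g. the reference
    geometry), with atom labels in the comment metadata omitted."""
    with open(path, "w") as fh:
        fh.write(f"{graph.n_atoms}\n")
        fh.write(f"charge={graph.charge}\n")
        for a, p in zip(graph.atoms, positions):
            fh.write(f"{a.element} {p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")


def sha256_file(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(path, outputs, seed: int, config: dict) -> dict:
    """Run manifest: seed, configuration echo, and a content hash per output."""
    manifest = {
        "seed": seed,
        "config": config,
        "outputs": {
            str(Path(p).name): sha256_file(p) for p in outputs
        },
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
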