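"""File formats: xvg time series, window/state manifests, multi-model PDB.

Window time series use the two-column whitespace "time value" dialect with
'#' and '@' comment lines (xvg).  Manifests are YAML.  Structures and
trajectories are read and written through MDAnalysis; MDAnalysis works in
ångström, the package in nm, and the conversion happens here and nowhere
else.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .alchemical import LambdaSchedule, ReducedPotentialMatrix
from .geometry import Trajectory
from .umbrella import UmbrellaWindow

__all__ = [
    "read_xvg",
    "write_xvg",
    "read_window_manifest",
    "write_window_manifest",
    "read_reduced_potentials",
    "write_reduced_potentials",
    "load_pdb_trajectory",
    "write_pdb_trajectory",
]

NM_PER_ANGSTROM = 0.1


def read_xvg(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a two-column xvg-dialect file; returns (times, values)."""
    times, values = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line[0] in "#@":
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}: expected two columns, got {line!r}")
            times.append(float(parts[0]))
            values.append(float(parts[1]))
    if not times:
        raise ValueError(f"{path}: no data lines")
    return np.asarray(times), np.asarray(values)


def write_xvg(path, times: np.ndarray, values: np.ndarray, comment: str = "") -> None:
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        fh.write("@ xaxis label \"time (ns)\"\n@ yaxis label \"coordinate (nm)\"\n")
        for t, v in zip(times, values):
            fh.write(f"{t:.6g} {v:.8g}\n")


def read_window_manifest(path) -> list[UmbrellaWindow]:
    """Load umbrella windows from a YAML manifest.

    Layout::

        defaults: {force_constant: 1000.0, temperature: 323.0, equilibration_cutoff: 0.0}
        windows:
          - {path: win_000.xvg, center: 0.0}
          - {path: win_001.xvg, center: 0.05, force_constant: 500.0}

    Per-window keys override defaults; time-series paths are resolved
    relative to the manifest.
    """
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    defaults = doc.get("defaults", {})
    windows = []
    for entry in doc["windows"]:
        cfg = {**defaults, **entry}
        times, values = read_xvg(path.parent / cfg["path"])
        windows.append(
            UmbrellaWindow(
                center=float(cfg["center"]),
                force_constant=float(cfg.get("force_constant", 0.0)),
                temperature=float(cfg["temperature"]),
                samples=values,
                times=times,
                equilibration_cutoff=float(cfg.get("equilibration_cutoff", 0.0)),
            )
        )
    return windows


def write_window_manifest(directory, windows: Sequence[UmbrellaWindow]) -> Path:
    """Write windows as xvg files plus a manifest; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, w in enumerate(windows):
        name = f"window_{i:03d}.xvg"
        write_xvg(directory / name, w.times, w.samples, comment=f"umbrella window {i}")
        entries.append(
            {
                "path": name,
                "center": float(w.center),
                "force_constant": float(w.force_constant),
                "temperature": float(w.temperature),
                "equilibration_cutoff": float(w.equilibration_cutoff),
            }
        )
    manifest = directory / "windows.yaml"
    with open(manifest, "w") as fh:
        yaml.safe_dump({"windows": entries}, fh, sort_keys=False)
    return manifest


def write_reduced_potentials(directory, matrix: ReducedPotentialMatrix) -> Path:
    """Write one TSV per origin state (columns = evaluating states) + manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for k in range(matrix.n_states):
        s = matrix.state_slice(k)
        name = f"state_{k:03d}.tsv"
        frame = pd.DataFrame(
            matrix.u[:, s].T, columns=[f"u_at_state_{j}" for j in range(matrix.n_states)]
        )
        frame.to_csv(directory / name, sep="\t", index=False, float_format="%.10g")
        entries.append({"path": name, "n_samples": int(matrix.n_k[k])})
    manifest = directory / "states.yaml"
    doc = {
        "temperature": float(matrix.temperature),
        "states": entries,
    }
    if matrix.schedule is not None:
        doc["lambda"] = [float(v) for v in matrix.schedule.values]
        if matrix.schedule.phases is not None:
            doc["phases"] = list(matrix.schedule.phases)
    with open(manifest, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
    return manifest


def read_reduced_potentials(manifest_path) -> ReducedPotentialMatrix:
    """Load a reduced-potential matrix written by :func:`write_reduced_potentials`."""
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        doc = yaml.safe_load(fh)
    blocks = []
    n_k = []
    for entry in doc["states"]:
        frame = pd.read_csv(manifest_path.parent / entry["path"], sep="\t")
        blocks.append(frame.to_numpy().T)
        n_k.append(int(entry["n_samples"]))
    schedule = None
    if "lambda" in doc:
        phases = tuple(doc["phases"]) if "phases" in doc else None
        schedule = LambdaSchedule(values=tuple(doc["lambda"]), phases=phases)
    return ReducedPotentialMatrix(
        u=np.concatenate(blocks, axis=1),
        n_k=np.asarray(n_k),
        temperature=float(doc["temperature"]),
        schedule=schedule,
    )


def load_pdb_trajectory(path, dt_ns: float = 1.0) -> Trajectory:
    """Read a (multi-model) PDB into the package Trajectory container (nm).

    Only orthorhombic boxes are supported; anything with box angles away
    from 90° is rejected.  Frames without box information get a generous
    dummy box (no periodic effects within it).
    """
    import MDAnalysis as mda

    # multi-model PDBs usually carry one CRYST1 record before the first
    # MODEL; MDAnalysis does not always propagate it to per-frame
    # dimensions, so parse it directly as the fallback box
    cryst_box = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("CRYST1"):
                fields = line.split()
                lengths = np.array([float(v) for v in fields[1:4]])
                angles = np.array([float(v) for v in fields[4:7]])
                if not np.allclose(angles, 90.0, atol=1e-3):
                    raise ValueError(
                        f"{path}: triclinic box (angles {angles}) not supported; "
                        "orthorhombic minimum image only"
                    )
                if np.any(lengths > 0):
                    cryst_box = lengths * NM_PER_ANGSTROM
                break

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
        atoms = pd.DataFrame(
            {
                "name": u.atoms.names,
                "resid": u.atoms.resids,
                "resname": u.atoms.resnames,
                "chain": [seg or "A" for seg in getattr(u.atoms, "chainIDs", ["A"] * len(u.atoms))],
            }
        )
        positions = []
        boxes = []
        for ts in u.trajectory:
            positions.append(u.atoms.positions * NM_PER_ANGSTROM)
            dims = ts.dimensions
            if dims is None or not np.any(dims[:3]):
                boxes.append(cryst_box if cryst_box is not None else np.full(3, 1e6))
            else:
                if not np.allclose(dims[3:], 90.0, atol=1e-3):
                    raise ValueError(
                        f"{path}: triclinic box (angles {dims[3:]}) not supported; "
                        "orthorhombic minimum image only"
                    )
                boxes.append(dims[:3] * NM_PER_ANGSTROM)
    n = len(positions)
    return Trajectory(
        positions=np.asarray(positions),
        box=np.asarray(boxes),
        atoms=atoms,
        times=np.arange(n, dtype=float) * dt_ns,
        source=str(path),
    )


def write_pdb_trajectory(traj: Trajectory, path) -> None:
    """Write a Trajectory as a multi-model PDB via MDAnalysis (nm → Å)."""
    import MDAnalysis as mda

    n_atoms = traj.n_atoms
    resids = traj.atoms["resid"].to_numpy()
    _, res_index = np.unique(resids, return_inverse=True)
    n_res = res_index.max() + 1
    res_first = np.array([np.where(res_index == r)[0][0] for r in range(n_res)])

    u = mda.Universe.empty(
        n_atoms=n_atoms,
        n_residues=n_res,
        atom_resindex=res_index,
        residue_segindex=np.zeros(n_res, dtype=int),
        trajectory=True,
    )
    u.add_TopologyAttr("name", traj.atoms["name"].tolist())
    u.add_TopologyAttr("resname", traj.atoms["resname"].to_numpy()[res_first].tolist())
    u.add_TopologyAttr("resid", resids[res_first].tolist())
    u.add_TopologyAttr("chainIDs", [c[:1] for c in traj.atoms["chain"].astype(str)])

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms, multiframe=True) as writer:
            for i in range(traj.n_frames):
                u.atoms.positions = traj.positions[i] / NM_PER_ANGSTROM
                u.dimensions = np.concatenate(
                    [traj.box[i] / NM_PER_ANGSTROM, [90.0, 90.0, 90.0]]
                )
                writer.write(u.atoms)
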