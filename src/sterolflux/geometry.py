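"""Geometric and statistical probes on membrane-protein trajectories.

All coordinates are nm; boxes are orthorhombic (lengths only) and distances
use the minimum-image convention.  Boundary conventions are closed: a point
exactly on the cylinder radius or at ±half_length is counted inside.
Waters are represented by their oxygen atom, monatomic ions by their single
particle.

The in-memory container is a lightweight :class:`Trajectory` (positions
array + a per-atom metadata table); PDB reading/writing goes through
MDAnalysis (see :mod:`sterolflux.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Trajectory",
    "Frame",
    "CylinderRegion",
    "ContactTable",
    "DensityGrid",
    "select",
    "cylinder_counts",
    "ion_contact_fractions",
    "residue_occupancy",
    "min_ca_distance",
    "positional_rmsd",
    "water_density",
    "z_coordinate_series",
    "minimum_image_displacement",
]


@dataclass
class Trajectory:
    """Ordered frames of one system.

    positions : (n_frames, n_atoms, 3) array, nm.
    box : (n_frames, 3) orthorhombic box lengths, nm.
    atoms : DataFrame with columns name, resid, resname, chain (index = atom
        order); extra columns pass through untouched.
    times : frame times, ns.
    """

    positions: np.ndarray
    box: np.ndarray
    atoms: pd.DataFrame
    times: np.ndarray | None = None
    source: str = ""

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError("positions must have shape (n_frames, n_atoms, 3)")
        if self.positions.shape[0] < 1:
            raise ValueError("a trajectory needs at least one frame")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        self.box = np.asarray(self.box, dtype=float)
        if self.box.ndim == 1:
            self.box = np.tile(self.box, (self.n_frames, 1))
        if self.box.shape != (self.n_frames, 3):
            raise ValueError("box must have shape (n_frames, 3) or (3,)")
        if np.any(self.box <= 0):
            raise ValueError("box lengths must be positive")
        if len(self.atoms) != self.n_atoms:
            raise ValueError("atoms table must have one row per atom")
        if self.times is None:
            self.times = np.arange(self.n_frames, dtype=float)
        else:
            self.times = np.asarray(self.times, dtype=float)
            if self.times.shape != (self.n_frames,):
                raise ValueError("times must have one entry per frame")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[1]

    def frame(self, i: int) -> "Frame":
        return Frame(positions=self.positions[i], box=self.box[i], atoms=self.atoms)

    def __iter__(self):
        return (self.frame(i) for i in range(self.n_frames))


@dataclass(frozen=True)
class Frame:
    """A single frame view: positions (n_atoms, 3), box lengths, atom table."""

    positions: np.ndarray
    box: np.ndarray
    atoms: pd.DataFrame


def select(
    traj_or_atoms: Trajectory | pd.DataFrame,
    name: str | Sequence[str] | None = None,
    resname: str | Sequence[str] | None = None,
    resid: int | Sequence[int] | None = None,
    chain: str | Sequence[str] | None = None,
) -> np.ndarray:
    """Atom indices matching all given criteria (scalars or sequences)."""
    atoms = traj_or_atoms.atoms if isinstance(traj_or_atoms, Trajectory) else traj_or_atoms
    mask = np.ones(len(atoms), dtype=bool)
    for column, value in (("name", name), ("resname", resname), ("resid", resid), ("chain", chain)):
        if value is None:
            continue
        values = [value] if np.isscalar(value) or isinstance(value, str) else list(value)
        mask &= atoms[column].isin(values).to_numpy()
    return np.where(mask)[0]


def _as_indices(traj: Trajectory, selection) -> np.ndarray:
    """Accept an index array, a boolean mask, or a selection-kwargs mapping."""
    if isinstance(selection, Mapping):
        return select(traj, **selection)
    arr = np.asarray(selection)
    if arr.dtype == bool:
        return np.where(arr)[0]
    return arr.astype(int)


def minimum_image_displacement(delta: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap displacement vectors into the nearest periodic image (orthorhombic)."""
    return delta - box * np.round(delta / box)


@dataclass
class CylinderRegion:
    """A finite cylinder, optionally anchored to a per-frame Cα midpoint.

    ``center`` is either a fixed 3D point (nm) or the rule
    ("midpoint_ca", resid_a, resid_b), re-evaluated each frame from the two
    Cα positions.  ``axis`` defaults to the membrane normal (box z axis).
    """

    center: tuple | np.ndarray
    half_length: float = 2.0
    radius: float = 1.3
    axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    def __post_init__(self) -> None:
        if self.radius <= 0 or self.half_length <= 0:
            raise ValueError("radius and half_length must be positive")
        self.axis = np.asarray(self.axis, dtype=float)
        norm = np.linalg.norm(self.axis)
        if norm == 0:
            raise ValueError("cylinder axis must be nonzero")
        self.axis = self.axis / norm

    def center_in(self, frame: Frame) -> np.ndarray:
        if isinstance(self.center, tuple) and len(self.center) == 3 and self.center[0] == "midpoint_ca":
            _, ra, rb = self.center
            ia = select(frame.atoms, name="CA", resid=int(ra))
            ib = select(frame.atoms, name="CA", resid=int(rb))
            if ia.size == 0 or ib.size == 0:
                raise ValueError(f"anchor residue {ra if ia.size == 0 else rb} has no CA atom")
            return 0.5 * (frame.positions[ia[0]] + frame.positions[ib[0]])
        return np.asarray(self.center, dtype=float)

    def axial_radial(self, frame: Frame, indices: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Axial and radial coordinates of the selected atoms (minimum image)."""
        center = self.center_in(frame)
        delta = minimum_image_displacement(frame.positions[indices] - center, frame.box)
        axial = delta @ self.axis
        radial = np.linalg.norm(delta - axial[:, None] * self.axis[None, :], axis=1)
        return axial, radial

    def contains(self, frame: Frame, indices: np.ndarray, half: str = "both") -> np.ndarray:
        """Closed-boundary membership mask; ``half`` is 'EC', 'IC' or 'both'.

        EC (extracellular) is the positive axial half (axial > 0), IC the
        nonpositive one; 'both' spans ±half_length.
        """
        axial, radial = self.axial_radial(frame, indices)
        inside = (radial <= self.radius) & (np.abs(axial) <= self.half_length)
        if half == "both":
            return inside
        if half == "EC":
            return inside & (axial > 0)
        if half == "IC":
            return inside & (axial <= 0)
        raise ValueError("half must be 'EC', 'IC' or 'both'")


@dataclass
class CountsResult:
    """Per-frame region counts with a trailing-window summary."""

    counts: np.ndarray
    times: np.ndarray
    mean: float
    sd: float
    window: tuple[float, float] | None = None

    def summary(self) -> str:
        w = f" over t in [{self.window[0]:g}, {self.window[1]:g}] ns" if self.window else ""
        return f"counts: mean {self.mean:.2f} ± {self.sd:.2f} per frame{w}"


def cylinder_counts(
    traj: Trajectory,
    cylinder: CylinderRegion,
    selection,
    half: str = "both",
    time_window: float | None = None,
) -> CountsResult:
    """Count selected atoms inside a cylinder per frame.

    ``time_window`` restricts the mean ± SD summary to the trailing window
    of that duration (ns), e.g. the final 10 ns of each run; the per-frame
    series always covers the whole trajectory.
    """
    indices = _as_indices(traj, selection)
    if indices.size == 0:
        raise ValueError("selection matches no atoms")
    counts = np.array(
        [int(cylinder.contains(traj.frame(i), indices, half=half).sum()) for i in range(traj.n_frames)]
    )
    times = traj.times
    if time_window is not None:
        t1 = float(times.max())
        keep = times >= t1 - time_window
        window = (float(t1 - time_window), t1)
    else:
        keep = np.ones(traj.n_frames, dtype=bool)
        window = None
    sel = counts[keep]
    return CountsResult(
        counts=counts,
        times=times,
        mean=float(sel.mean()),
        sd=float(sel.std(ddof=1)) if sel.size > 1 else 0.0,
        window=window,
    )


@dataclass
class ContactTable:
    """Residue–ion contact fractions (% of frames within cutoff), sorted descending."""

    table: pd.DataFrame           # columns: resid, resname, fraction_pct
    cutoff: float
    report_threshold: float

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.1f")

    def summary(self) -> str:
        lines = [f"contacts within {self.cutoff:g} nm (rows <{self.report_threshold:g}% excluded)"]
        for _, row in self.table.iterrows():
            lines.append(f"  {row.resname}{int(row.resid)}  {row.fraction_pct:.1f}%")
        return "\n".join(lines)


def _min_dist_to_group(traj: Trajectory, frame_idx: int, a_idx: np.ndarray, b_idx: np.ndarray) -> float:
    fr = traj.frame(frame_idx)
    delta = fr.positions[a_idx][:, None, :] - fr.positions[b_idx][None, :, :]
    delta = minimum_image_displacement(delta, fr.box)
    return float(np.sqrt((delta**2).sum(axis=2)).min())


def ion_contact_fractions(
    traj: Trajectory,
    ion_selection,
    residue_set: Sequence[int],
    cutoff: float = 0.3,
    report_threshold: float = 1.0,
    side_chain_only: bool = False,
) -> ContactTable:
    """Percentage of frames in which each residue touches the ion.

    A residue is in contact in a frame when the minimum distance between
    the ion and any of the residue's atoms (all atoms by default;
    backbone N/CA/C/O excluded with ``side_chain_only``) is ≤ cutoff.
    Residues below ``report_threshold`` (%) are dropped; the table is
    sorted by descending fraction.
    """
    if len(residue_set) == 0:
        raise ValueError("residue_set must not be empty")
    ion_idx = _as_indices(traj, ion_selection)
    if ion_idx.size == 0:
        raise ValueError("ion selection matches no atoms")
    rows = []
    backbone = {"N", "CA", "C", "O"}
    for resid in residue_set:
        res_idx = select(traj, resid=int(resid))
        if side_chain_only:
            names = traj.atoms["name"].to_numpy()[res_idx]
            res_idx = res_idx[[n not in backbone for n in names]]
        if res_idx.size == 0:
            raise ValueError(f"residue {resid} matches no atoms")
        hits = sum(
            _min_dist_to_group(traj, i, ion_idx, res_idx) <= cutoff for i in range(traj.n_frames)
        )
        resname = str(traj.atoms["resname"].iloc[res_idx[0]])
        rows.append((int(resid), resname, 100.0 * hits / traj.n_frames))
    df = pd.DataFrame(rows, columns=["resid", "resname", "fraction_pct"])
    df = df[df.fraction_pct >= report_threshold]
    df = df.sort_values("fraction_pct", ascending=False, kind="stable").reset_index(drop=True)
    return ContactTable(table=df, cutoff=cutoff, report_threshold=report_threshold)


def residue_occupancy(
    trajectories: Trajectory | Sequence[Trajectory],
    ligand_selection,
    cutoff: float = 0.6,
    top_k: int | None = None,
) -> pd.DataFrame:
    """Fraction of pooled frames each residue spends within cutoff of the ligand.

    Multiple trajectories (e.g. the umbrella windows flanking an energetic
    peak) are pooled frame-wise.  Returns resid, resname, occupancy (0–1)
    sorted descending, optionally truncated to the top k residues.
    """
    trajs = [trajectories] if isinstance(trajectories, Trajectory) else list(trajectories)
    if not trajs:
        raise ValueError("at least one trajectory is required")
    occupancy: dict[int, int] = {}
    resnames: dict[int, str] = {}
    total_frames = 0
    for traj in trajs:
        lig_idx = _as_indices(traj, ligand_selection)
        if lig_idx.size == 0:
            raise ValueError("ligand selection matches no atoms")
        protein = traj.atoms.drop(index=lig_idx)
        resids = sorted(protein["resid"].unique())
        total_frames += traj.n_frames
        for resid in resids:
            res_idx = select(traj, resid=int(resid))
            res_idx = np.setdiff1d(res_idx, lig_idx)
            if res_idx.size == 0:
                continue
            hits = sum(
                _min_dist_to_group(traj, i, lig_idx, res_idx) <= cutoff
                for i in range(traj.n_frames)
            )
            occupancy[resid] = occupancy.get(resid, 0) + hits
            resnames.setdefault(resid, str(traj.atoms["resname"].iloc[res_idx[0]]))
    df = pd.DataFrame(
        {
            "resid": list(occupancy),
            "resname": [resnames[r] for r in occupancy],
            "occupancy": [occupancy[r] / total_frames for r in occupancy],
        }
    ).sort_values("occupancy", ascending=False, kind="stable").reset_index(drop=True)
    return df.head(top_k) if top_k else df


@dataclass
class DistanceSeries:
    """Per-frame distance between two atoms, with summary statistics."""

    distances: np.ndarray
    times: np.ndarray
    mean: float
    sd: float

    def summary(self) -> str:
        return f"distance: mean {self.mean:.3f} ± {self.sd:.3f} nm over {self.distances.size} frames"


def min_ca_distance(traj: Trajectory, residue_a: int, residue_b: int) -> DistanceSeries:
    """Minimum-image Cα–Cα distance between two residues, per frame."""
    ia = select(traj, name="CA", resid=int(residue_a))
    ib = select(traj, name="CA", resid=int(residue_b))
    if ia.size == 0 or ib.size == 0:
        missing = residue_a if ia.size == 0 else residue_b
        raise ValueError(f"residue {missing} has no CA atom")
    delta = traj.positions[:, ia[0], :] - traj.positions[:, ib[0], :]
    delta = minimum_image_displacement(delta, traj.box)
    d = np.linalg.norm(delta, axis=1)
    return DistanceSeries(
        distances=d,
        times=traj.times,
        mean=float(d.mean()),
        sd=float(d.std(ddof=1)) if d.size > 1 else 0.0,
    )


def positional_rmsd(
    trajectories: Trajectory | Sequence[Trajectory],
    selection,
    reference: np.ndarray | None = None,
    center: bool = False,
) -> tuple[float, float, list[np.ndarray]]:
    """Positional RMSD of a selection versus its first-frame position.

    No rotational fitting (appropriate for single ions); ``center``
    optionally removes the selection centroid before comparing.  Over
    several replicate trajectories returns (mean, SD) of the per-replicate
    mean RMSD plus each per-frame series.
    """
    trajs = [trajectories] if isinstance(trajectories, Trajectory) else list(trajectories)
    per_replicate = []
    series = []
    for traj in trajs:
        idx = _as_indices(traj, selection)
        if idx.size == 0:
            raise ValueError("selection matches no atoms")
        ref = traj.positions[0, idx] if reference is None else np.asarray(reference, dtype=float)
        pos = traj.positions[:, idx, :]
        if center:
            pos = pos - pos.mean(axis=1, keepdims=True)
            ref = ref - ref.mean(axis=0, keepdims=True)
        rmsd = np.sqrt(((pos - ref[None]) ** 2).sum(axis=2).mean(axis=1))
        series.append(rmsd)
        per_replicate.append(float(rmsd.mean()))
    mean = float(np.mean(per_replicate))
    sd = float(np.std(per_replicate, ddof=1)) if len(per_replicate) > 1 else 0.0
    return mean, sd, series


@dataclass
class DensityGrid:
    """Time-averaged occupancy on a regular grid (counts per voxel per frame)."""

    origin: np.ndarray
    spacing: float
    occupancy: np.ndarray

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if np.any(self.occupancy < 0):
            raise ValueError("occupancy must be nonnegative")

    @property
    def total_mass(self) -> float:
        """Sum over voxels = mean selected-atom count per frame (conservation)."""
        return float(self.occupancy.sum())

    def write_dx(self, path) -> None:
        """Write the grid in OpenDX plain-text format (as visualization tools read)."""
        nx, ny, nz = self.occupancy.shape
        ox, oy, oz = self.origin
        d = self.spacing
        with open(path, "w") as fh:
            fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
            fh.write(f"origin {ox:.6f} {oy:.6f} {oz:.6f}\n")
            fh.write(f"delta {d:.6f} 0 0\ndelta 0 {d:.6f} 0\ndelta 0 0 {d:.6f}\n")
            fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
            fh.write(
                f"object 3 class array type double rank 0 items {nx * ny * nz} data follows\n"
            )
            flat = self.occupancy.ravel(order="C")
            for i in range(0, flat.size, 3):
                fh.write(" ".join(f"{v:.6g}" for v in flat[i : i + 3]) + "\n")
            fh.write('attribute "dep" string "positions"\n')
            fh.write('object "density" class field\n')


def water_density(traj: Trajectory, selection, spacing: float) -> DensityGrid:
    """Time-averaged spatial density of a selection on a regular grid.

    Atoms are wrapped into the primary box of each frame; the grid covers
    the largest box.  Voxel values are mean counts per frame, so the grid
    total equals the mean selected-atom count per frame exactly.
    """
    idx = _as_indices(traj, selection)
    if idx.size == 0:
        raise ValueError("selection matches no atoms")
    box_max = traj.box.max(axis=0)
    if spacing > box_max.min():
        raise ValueError("spacing exceeds the box; choose a finer grid")
    shape = np.maximum(np.ceil(box_max / spacing).astype(int), 1)
    grid = np.zeros(shape)
    for i in range(traj.n_frames):
        pos = np.mod(traj.positions[i, idx], traj.box[i])
        cells = np.minimum((pos / spacing).astype(int), shape - 1)
        np.add.at(grid, (cells[:, 0], cells[:, 1], cells[:, 2]), 1.0)
    grid /= traj.n_frames
    return DensityGrid(origin=np.zeros(3), spacing=spacing, occupancy=grid)


def z_coordinate_series(
    traj: Trajectory,
    selections: Mapping[str, object],
    region: CylinderRegion,
) -> pd.DataFrame:
    """Axial coordinates of region-resident atoms, one row per atom per frame.

    ``selections`` maps a species label (e.g. 'water', 'Na+', 'Cl-') to a
    selection; only atoms inside the region in a given frame are recorded.
    Returns a DataFrame with columns time, species, z (axial coordinate,
    nm, relative to the region center).
    """
    records = []
    for species, sel in selections.items():
        idx = _as_indices(traj, sel)
        for i in range(traj.n_frames):
            frame = traj.frame(i)
            if idx.size == 0:
                continue
            inside = region.contains(frame, idx)
            axial, _ = region.axial_radial(frame, idx)
            for z in axial[inside]:
                records.append((float(traj.times[i]), species, float(z)))
    return pd.DataFrame(records, columns=["time", "species", "z"])
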