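"""Synthetic inputs with known ground truth for every pipeline stage.

Three generator families mirror the data the analysis layer consumes:

* biased reaction-coordinate samples from analytic 1D potentials (Metropolis
  Monte Carlo under the umbrella bias), the oracle for WHAM;
* λ-coupled harmonic systems with closed-form free-energy differences
  (exact Gaussian sampling), the oracle for MBAR/BAR;
* toy membrane-protein trajectories with planted waters, ions and helix
  scaffolds, the oracle for the geometry probes.

Every generator is deterministic under a fixed seed and returns its ground
truth alongside the data, so downstream assertions never re-derive it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .alchemical import LambdaSchedule, ReducedPotentialMatrix
from .constants import DEFAULT_ATOMISTIC_TEMPERATURE, DEFAULT_CG_TEMPERATURE, kt_kj
from .geometry import CylinderRegion, Trajectory
from .umbrella import UmbrellaWindow

__all__ = [
    "AnalyticPotential",
    "FlatPotential",
    "HarmonicPotential",
    "DoubleWellPotential",
    "WellPlateauPotential",
    "LambdaHarmonicModel",
    "ToyTrajectorySpec",
    "gen_umbrella_windows",
    "gen_reduced_potentials",
    "gen_toy_trajectory",
]


# ---------------------------------------------------------------------------
# analytic 1D potentials (stand-ins for the force-field free-energy landscape)


@dataclass(frozen=True)
class AnalyticPotential:
    """A bounded analytic 1D potential U(x), kJ·mol⁻¹ over x in nm."""

    def __call__(self, x):
        raise NotImplementedError

    def profile(self, x: np.ndarray) -> np.ndarray:
        """U evaluated on a grid, shifted so its minimum is zero."""
        u = np.asarray(self(np.asarray(x, dtype=float)))
        return u - u.min()


@dataclass(frozen=True)
class FlatPotential(AnalyticPotential):
    """U(x) = 0 everywhere; unbiased sampling is uniform."""

    def __call__(self, x):
        return np.zeros_like(np.asarray(x, dtype=float))


@dataclass(frozen=True)
class HarmonicPotential(AnalyticPotential):
    """U(x) = ½ k (x − x0)²."""

    k: float = 100.0
    x0: float = 0.5

    def __call__(self, x):
        return 0.5 * self.k * (np.asarray(x, dtype=float) - self.x0) ** 2


@dataclass(frozen=True)
class DoubleWellPotential(AnalyticPotential):
    """Quartic double well: U = B ((x − c)²/w² − 1)².

    Minima at c ± w (U = 0), barrier of height B at x = c.
    """

    barrier: float = 20.0
    center: float = 0.5
    half_separation: float = 0.25

    def __call__(self, x):
        t = ((np.asarray(x, dtype=float) - self.center) / self.half_separation) ** 2
        return self.barrier * (t - 1.0) ** 2

    @property
    def minima(self) -> tuple[float, float]:
        return (self.center - self.half_separation, self.center + self.half_separation)


@dataclass(frozen=True)
class WellPlateauPotential(AnalyticPotential):
    """A binding well rising smoothly to a flat plateau.

    Emulates the shape of extracting a lipid from a favorable environment
    into bulk: U = depth · sigmoid((x − edge)/width) − depth, so the well
    floor sits at −depth relative to the plateau at large x.
    """

    depth: float = 83.0
    edge: float = 0.5
    width: float = 0.1

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        s = 1.0 / (1.0 + np.exp(-(x - self.edge) / self.width))
        return self.depth * s - self.depth

    @property
    def well_depth(self) -> float:
        return self.depth


# ---------------------------------------------------------------------------
# umbrella-window generator


def gen_umbrella_windows(
    potential: AnalyticPotential,
    centers: Sequence[float],
    force_constant: float = 1000.0,
    n_samples: int = 5000,
    temperature: float = DEFAULT_CG_TEMPERATURE,
    seed: int | None = None,
    burn_in: int = 2000,
    thin: int = 5,
) -> list[UmbrellaWindow]:
    """Metropolis Monte-Carlo umbrella sampling of an analytic potential.

    Each window samples the biased potential U(x) + ½k(x − c)² at the given
    temperature.  The proposal step is auto-tuned toward ~40 % acceptance
    during a discarded burn-in; a window whose final acceptance falls
    outside (0.05, 0.95) triggers a warning with a suggested step size.
    Deterministic per seed.  Defaults mirror the study conditions for
    coarse-grained profiles: k = 1000 kJ·mol⁻¹·nm⁻², T = 323 K.
    """
    if force_constant < 0:
        raise ValueError("force_constant must be nonnegative")
    rng = np.random.default_rng(seed)
    centers = np.asarray(centers, dtype=float)
    kt = kt_kj(temperature)
    n_windows = centers.size

    def biased(x: np.ndarray) -> np.ndarray:
        return np.asarray(potential(x)) + 0.5 * force_constant * (x - centers) ** 2

    # initial proposal width: thermal width of the bias (or a coarse default)
    if force_constant > 0:
        step = np.full(n_windows, np.sqrt(kt / force_constant))
    else:
        span = max(float(np.ptp(centers)), 1.0) if n_windows > 1 else 1.0
        step = np.full(n_windows, 0.25 * span)

    x = centers.copy()
    energy = biased(x)

    accepted = np.zeros(n_windows)
    tune_block = 200
    for i in range(burn_in):
        prop = x + rng.normal(0.0, step, n_windows)
        e_prop = biased(prop)
        accept = rng.random(n_windows) < np.exp(np.minimum(0.0, -(e_prop - energy) / kt))
        x = np.where(accept, prop, x)
        energy = np.where(accept, e_prop, energy)
        accepted += accept
        if (i + 1) % tune_block == 0:
            rate = accepted / tune_block
            step *= np.clip(rate / 0.40, 0.5, 2.0)
            accepted[:] = 0.0

    samples = np.empty((n_windows, n_samples))
    accepted[:] = 0.0
    total_steps = n_samples * thin
    for i in range(total_steps):
        prop = x + rng.normal(0.0, step, n_windows)
        e_prop = biased(prop)
        accept = rng.random(n_windows) < np.exp(np.minimum(0.0, -(e_prop - energy) / kt))
        x = np.where(accept, prop, x)
        energy = np.where(accept, e_prop, energy)
        accepted += accept
        if (i + 1) % thin == 0:
            samples[:, (i + 1) // thin - 1] = x

    rate = accepted / total_steps
    bad = (rate <= 0.05) | (rate >= 0.95)
    if bad.any():
        j = int(np.where(bad)[0][0])
        suggestion = step[j] * (0.5 if rate[j] <= 0.05 else 2.0)
        warnings.warn(
            f"window {j} (center {centers[j]:.3f}) acceptance {rate[j]:.2f} outside "
            f"(0.05, 0.95); consider a proposal step near {suggestion:.3g} nm",
            RuntimeWarning,
            stacklevel=2,
        )

    return [
        UmbrellaWindow(
            center=float(c),
            force_constant=force_constant,
            temperature=temperature,
            samples=samples[i],
        )
        for i, c in enumerate(centers)
    ]


# ---------------------------------------------------------------------------
# λ-coupled harmonic model for alchemical estimators


@dataclass(frozen=True)
class LambdaHarmonicModel:
    """A 1D harmonic oscillator whose stiffness follows a λ schedule.

    Stiffness interpolates geometrically, k(λ) = k0^(1−λ) k1^λ (always
    positive), optionally with a mean shift μ(λ) = (1−λ)μ0 + λμ1.  The
    reduced free-energy difference between states has the closed form
    Δf(i→j) = ½ ln(k_j / k_i): only stiffness changes the partition
    function of a 1D Gaussian, mean shifts do not.
    """

    k_initial: float
    k_final: float
    mu_initial: float = 0.0
    mu_final: float = 0.0

    def __post_init__(self) -> None:
        if self.k_initial <= 0 or self.k_final <= 0:
            raise ValueError("stiffness must be positive at every λ")

    def stiffness(self, lam: np.ndarray) -> np.ndarray:
        lam = np.asarray(lam, dtype=float)
        return self.k_initial ** (1.0 - lam) * self.k_final**lam

    def mean(self, lam: np.ndarray) -> np.ndarray:
        lam = np.asarray(lam, dtype=float)
        return (1.0 - lam) * self.mu_initial + lam * self.mu_final

    def analytic_delta_f(self, lam_from: float, lam_to: float) -> float:
        """Closed-form reduced Δf between two λ points."""
        k0, k1 = self.stiffness(np.array([lam_from, lam_to]))
        return 0.5 * float(np.log(k1 / k0))


def gen_reduced_potentials(
    model: LambdaHarmonicModel,
    schedule: LambdaSchedule,
    n_per_state: int = 1000,
    temperature: float = DEFAULT_CG_TEMPERATURE,
    seed: int | None = None,
) -> tuple[ReducedPotentialMatrix, np.ndarray]:
    """Exact Boltzmann samples of a λ-harmonic system, evaluated at all states.

    Sampling is exact (each state's distribution is Gaussian with variance
    kT/k(λ)), so estimator tests face statistical noise only.  Returns the
    reduced-potential matrix and the analytic reduced free energies per
    state (anchored at state 0).
    """
    lam = np.asarray(schedule.values, dtype=float)
    k = model.stiffness(lam)          # kJ/mol/nm^2 per state
    mu = model.mean(lam)
    kt = kt_kj(temperature)
    rng = np.random.default_rng(seed)

    sigmas = np.sqrt(kt / k)
    xs = [rng.normal(mu[i], sigmas[i], n_per_state) for i in range(lam.size)]
    x_all = np.concatenate(xs)
    # reduced potential of every pooled sample at every state
    u = 0.5 * k[:, None] * (x_all[None, :] - mu[:, None]) ** 2 / kt
    matrix = ReducedPotentialMatrix(
        u=u,
        n_k=np.full(lam.size, n_per_state),
        temperature=temperature,
        schedule=schedule,
    )
    analytic_f = 0.5 * np.log(k / k[0])
    return matrix, analytic_f


# ---------------------------------------------------------------------------
# toy membrane-protein trajectories


@dataclass
class ToyTrajectorySpec:
    """Recipe for a planted-geometry trajectory.

    Two straight "helices" of Cα atoms run along z; their inter-axis
    distance follows ``helix_distance_schedule`` (one value per frame,
    emulating the pinching of intracellular helix ends).  Waters are placed
    with known in/out status relative to ``cylinder`` (per half), and one
    cation follows an approach-and-bind path that is within
    ``contact_cutoff`` of a target residue atom for exactly the frames in
    ``ion_bound_frames``.
    """

    n_frames: int = 15
    box: tuple[float, float, float] = (10.0, 10.0, 10.0)
    cylinder: CylinderRegion | None = None
    waters_inside_ec: int = 3
    waters_inside_ic: int = 4
    waters_outside: int = 10
    helix_residues: int = 8
    helix_distance_schedule: Sequence[float] | None = None
    ion_bound_frames: Sequence[int] | None = None
    contact_cutoff: float = 0.3
    jitter: float = 0.0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("need at least one frame")
        if any(b <= 0 for b in self.box):
            raise ValueError("box lengths must be positive")
        if self.cylinder is None:
            # the TMD probe geometry: 4 nm long, 1.3 nm radius, box center
            self.cylinder = CylinderRegion(
                center=np.array(self.box) / 2.0, half_length=2.0, radius=1.3
            )
        if self.helix_distance_schedule is None:
            self.helix_distance_schedule = np.full(self.n_frames, 2.0)
        self.helix_distance_schedule = np.asarray(self.helix_distance_schedule, dtype=float)
        if self.helix_distance_schedule.size != self.n_frames:
            raise ValueError("helix_distance_schedule needs one value per frame")
        if self.ion_bound_frames is None:
            self.ion_bound_frames = list(range(1, self.n_frames))


def _place_in_cylinder(rng, cyl: CylinderRegion, n: int, half: str) -> np.ndarray:
    """Uniform points strictly inside a cylinder half (margin keeps them off edges)."""
    r = cyl.radius * 0.9 * np.sqrt(rng.random(n))
    theta = rng.random(n) * 2 * np.pi
    if half == "EC":
        z = rng.uniform(0.05, cyl.half_length * 0.9, n)
    else:
        z = rng.uniform(-cyl.half_length * 0.9, -0.05, n)
    center = np.asarray(cyl.center, dtype=float)
    pts = np.stack([r * np.cos(theta), r * np.sin(theta), z], axis=1)
    return center + pts


def gen_toy_trajectory(spec: ToyTrajectorySpec, seed: int | None = None) -> tuple[Trajectory, dict]:
    """Build a planted trajectory and the ground truth of every probe on it.

    The returned truth dict carries per-frame extracellular/intracellular
    water counts in the probe cylinder, the ion's in-contact frames and its
    contact fraction (%), the planted helix inter-axis distances, and the
    ion's planted displacement from its initial position per frame.
    """
    rng = np.random.default_rng(seed)
    cyl = spec.cylinder
    center = np.asarray(cyl.center, dtype=float)
    box = np.asarray(spec.box, dtype=float)
    n_frames = spec.n_frames

    atom_rows: list[tuple] = []   # (name, resid, resname, chain)
    frames: list[list[np.ndarray]] = [[] for _ in range(n_frames)]
    resid = 0

    # helix A and B: straight CA strands along z, symmetric about the center
    n_res = spec.helix_residues
    z_span = np.linspace(-1.5, 1.5, n_res)
    helix_resids: dict[str, list[int]] = {"A": [], "B": []}
    for chain, sign in (("A", -1.0), ("B", +1.0)):
        for j in range(n_res):
            resid += 1
            helix_resids[chain].append(resid)
            atom_rows.append(("CA", resid, "ALA", chain))
            for t in range(n_frames):
                d = spec.helix_distance_schedule[t]
                jit = rng.normal(0.0, spec.jitter, 3) if spec.jitter > 0 else 0.0
                pos = center + np.array([sign * d / 2.0, 0.0, z_span[j]]) + jit
                frames[t].append(pos)

    # the ion's binding target: the first residue of helix A (its CA atom)
    target_resid = helix_resids["A"][0]
    target_pos = np.array(
        [
            center
            + np.array([-spec.helix_distance_schedule[t] / 2.0, 0.0, z_span[0]])
            for t in range(n_frames)
        ]
    )

    # cation: far from the target when unbound, 0.2 nm away when bound
    resid += 1
    ion_resid = resid
    atom_rows.append(("NA", ion_resid, "NA", "I"))
    bound = set(int(i) for i in spec.ion_bound_frames)
    far_point = center + np.array([0.0, box[1] * 0.35, 0.0])
    ion_positions = []
    for t in range(n_frames):
        if t in bound:
            pos = target_pos[t] + np.array([0.0, 0.0, -0.2])
        else:
            pos = far_point
        ion_positions.append(pos)
        frames[t].append(pos)

    # a chloride parked outside the cylinder
    resid += 1
    atom_rows.append(("CL", resid, "CL", "I"))
    cl_pos = center + np.array([0.0, -box[1] * 0.35, 0.0])
    for t in range(n_frames):
        frames[t].append(cl_pos)

    # waters with planted in/out status (per frame, re-drawn positions)
    n_w = spec.waters_inside_ec + spec.waters_inside_ic + spec.waters_outside
    water_resids = []
    for j in range(n_w):
        resid += 1
        water_resids.append(resid)
        atom_rows.append(("OW", resid, "SOL", "W"))
    for t in range(n_frames):
        ec = _place_in_cylinder(rng, cyl, spec.waters_inside_ec, "EC")
        ic = _place_in_cylinder(rng, cyl, spec.waters_inside_ic, "IC")
        out = []
        while len(out) < spec.waters_outside:
            p = rng.uniform(0.0, box, 3)
            delta = p - center
            axial = delta[2]
            radial = np.hypot(delta[0], delta[1])
            if radial > cyl.radius + 0.2 or abs(axial) > cyl.half_length + 0.2:
                out.append(p)
        for p in np.concatenate([ec, ic, np.asarray(out)], axis=0):
            frames[t].append(p)

    positions = np.array([np.stack(f) for f in frames])
    atoms = pd.DataFrame(atom_rows, columns=["name", "resid", "resname", "chain"])
    traj = Trajectory(
        positions=positions,
        box=box,
        atoms=atoms,
        times=np.arange(n_frames, dtype=float),
        source="synthetic toy trajectory",
    )

    ion_disp = np.linalg.norm(np.array(ion_positions) - ion_positions[0], axis=1)
    truth = {
        "waters_ec_per_frame": [spec.waters_inside_ec] * n_frames,
        "waters_ic_per_frame": [spec.waters_inside_ic] * n_frames,
        "ion_resid": ion_resid,
        "ion_target_resid": target_resid,
        "ion_bound_frames": sorted(bound),
        "ion_contact_fraction_pct": 100.0 * len(bound) / n_frames,
        "helix_a_resids": helix_resids["A"],
        "helix_b_resids": helix_resids["B"],
        "helix_distances": spec.helix_distance_schedule.tolist(),
        "ion_displacement_per_frame": ion_disp.tolist(),
        "water_resids": water_resids,
    }
    return traj, truth
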