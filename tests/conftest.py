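"""Shared fixtures: seeded synthetic datasets reused across test modules."""

import numpy as np
import pytest

import sterolflux as sf


@pytest.fixture(scope="session")
def harmonic_umbrella():
    """21 umbrella windows over U(x) = 50 (x − 0.5)² at the study settings."""
    potential = sf.HarmonicPotential(k=100.0, x0=0.5)
    centers = np.arange(0.0, 1.0001, 0.05)
    windows = sf.gen_umbrella_windows(
        potential, centers, force_constant=1000.0, n_samples=5000, temperature=323.0, seed=101
    )
    return potential, windows


@pytest.fixture(scope="session")
def harmonic_lambda_matrix():
    """5 λ states of a harmonic system with fourfold stiffness change (ΔF = RT ln 2)."""
    model = sf.LambdaHarmonicModel(k_initial=400.0, k_final=1600.0)
    schedule = sf.LambdaSchedule(tuple(np.linspace(0.0, 1.0, 5)))
    matrix, analytic_f = sf.gen_reduced_potentials(
        model, schedule, n_per_state=10_000, temperature=323.0, seed=202
    )
    return matrix, analytic_f


@pytest.fixture(scope="session")
def toy_trajectory():
    """Planted toy trajectory: 15 frames, ion bound in 14, fixed helix gap."""
    spec = sf.ToyTrajectorySpec(n_frames=15, ion_bound_frames=list(range(1, 15)))
    traj, truth = sf.gen_toy_trajectory(spec, seed=303)
    return spec, traj, truth
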