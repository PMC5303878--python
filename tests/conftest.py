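"""Shared fixtures: the coarsening runs reused across scaling/collapse tests.

The heavy trajectories (256x256 lattices run deep into the coarsening
regime) are session-scoped so that the scaling, collapse and acceptance
tests all analyse the same runs.
"""

from __future__ import annotations

import numpy as np
import pytest

from t6phase.core_io import FieldState, make_rng
from t6phase.ibm import IBMParams, run_ibm
from t6phase.ising import IsingParams, run_ising
from t6phase.pde import TwoStrainParams, integrate

IBM_STEPS = [50, 100, 200, 400, 800, 1600, 3200]
ISING_SWEEPS = [5, 10, 20, 40, 80, 160, 320]
PDE_TIMES = [12.5, 25.0, 50.0, 100.0, 200.0, 400.0]


@pytest.fixture(scope="session")
def ibm_coarsening_runs() -> dict[int, dict[int, np.ndarray]]:
    """Snapshot grids of 256x256 mutual-killing runs for seeds 1..3."""
    out = {}
    for seed in (1, 2, 3):
        params = IBMParams(width=256, height=256, seed=seed, boundary="periodic")
        snaps, _ = run_ibm(params, n_steps=IBM_STEPS[-1], record_steps=IBM_STEPS)
        out[seed] = {s: snaps[s].grid for s in IBM_STEPS}
    return out


@pytest.fixture(scope="session")
def ising_coarsening_runs() -> dict[int, dict[int, np.ndarray]]:
    """Snapshot spins of 256x256 Ising quenches (beta=1) for seeds 1..3."""
    out = {}
    for seed in (1, 2, 3):
        params = IsingParams(width=256, height=256, beta=1.0, seed=seed)
        snaps, _ = run_ising(params, n_sweeps=ISING_SWEEPS[-1], record_sweeps=ISING_SWEEPS)
        out[seed] = {s: snaps[s].spins for s in ISING_SWEEPS}
    return out


def binary_two_strain_state(
    params: TwoStrainParams, n: int, dx: float, seed: int, freq: float = 0.5
) -> FieldState:
    """Random per-cell genotype assignment at density r/s (lattice-like seeding)."""
    rng = make_rng(seed, "pde-init")
    dens = params.r / params.s
    is_a = rng.random((n, n)) < freq
    return FieldState(A=np.where(is_a, dens, 0.0), B=np.where(is_a, 0.0, dens), dx=dx)


@pytest.fixture(scope="session")
def pde_coarsening_runs() -> dict[int, dict[float, np.ndarray]]:
    """Thresholded composition images of 256x256 two-strain PDE runs, seeds 1..2."""
    params = TwoStrainParams()
    out = {}
    for seed in (1, 2):
        state = binary_two_strain_state(params, n=256, dx=0.1, seed=seed)
        traj = integrate(state, params, t_end=PDE_TIMES[-1], dt=0.02, record_times=PDE_TIMES)
        out[seed] = {
            snap.t: np.where(snap.composition() >= 0.5, 1, -1).astype(np.int8)
            for snap in traj
            if snap.t in PDE_TIMES
        }
    return out
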