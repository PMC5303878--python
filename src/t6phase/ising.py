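"""Ising spin model with an eight-neighbour Hamiltonian and Glauber-style flips.

This is the statistical-mechanics reference point for the killing models:
a non-conserved order parameter relaxing by single-spin flips ("Model A").
The local Hamiltonian at a site is the sum of its eight nearest neighbours
multiplied by the centre spin, so it is +8 for a spin surrounded by its own
type and -8 for one surrounded by the opposite type.  Because flipping one
spin only negates its local Hamiltonian, the energy difference of a flip is
``dE = 2 * H_old`` (in units of k_B*T); the spin flips iff
``exp(-beta * dE)`` exceeds a uniform draw on [0, 1).  A sweep is W*H flip
attempts at uniformly random sites, after which one time step has passed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._kernels import ising_sweep_kernel
from .core_io import RunConfig, SpinLattice, make_rng, write_snapshot

__all__ = [
    "IsingParams",
    "local_hamiltonian",
    "flip_probability",
    "attempt_flip",
    "sweep",
    "run_ising",
]

_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass
class IsingParams:
    """Lattice size and inverse temperature (in 1/(k_B*T); default unity)."""

    width: int = 500
    height: int = 500
    beta: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.width < 1 or self.height < 1:
            raise ValueError("lattice dimensions must be positive")


def local_hamiltonian(spins: SpinLattice, site: tuple[int, int]) -> int:
    """Sum of the eight neighbours times the centre spin (periodic lookup).

    Ranges over the even integers -8..8: +8 fully aligned, -8 fully
    anti-aligned.
    """
    i, j = site
    H, W = spins.shape
    if not (0 <= i < H and 0 <= j < W):
        raise IndexError(f"site {site} out of bounds for {H}x{W} lattice")
    s = spins.spins
    total = sum(int(s[(i + di) % H, (j + dj) % W]) for di, dj in _OFFSETS)
    return total * int(s[i, j])


def flip_probability(h_old: int, beta: float) -> float:
    """Probability that a flip with local Hamiltonian ``h_old`` is accepted.

    The acceptance weight is exp(-beta * dE) with dE = 2*h_old, compared
    against a uniform draw u in [0, 1); since u < 1, any weight >= 1 (i.e.
    any energetically non-increasing move, h_old <= 0) is always accepted.
    """
    return float(min(1.0, np.exp(-2.0 * beta * h_old)))


def _acceptance_table(beta: float) -> np.ndarray:
    # raw (uncapped) weights exp(-2*beta*H) for H = -8..8; comparison with
    # u < 1 makes capping at 1 irrelevant
    return np.exp(-2.0 * beta * np.arange(-8, 9, dtype=np.float64))


def attempt_flip(
    spins: SpinLattice,
    site: tuple[int, int],
    params: IsingParams,
    rng: np.random.Generator,
) -> bool:
    """Attempt one stochastic flip at ``site``; mutates the lattice in place."""
    h_old = local_hamiltonian(spins, site)
    u = rng.random()
    if np.exp(-2.0 * params.beta * h_old) > u:
        spins.spins[site] = -spins.spins[site]
        return True
    return False


def sweep(spins: SpinLattice, params: IsingParams, rng: np.random.Generator) -> int:
    """One time step: W*H flip attempts at uniform random sites (with replacement).

    Returns the number of accepted flips and increments the sweep counter.
    """
    H, W = spins.shape
    n = H * W
    rows = rng.integers(0, H, size=n)
    cols = rng.integers(0, W, size=n)
    us = rng.random(n)
    flips = ising_sweep_kernel(spins.spins, rows, cols, us, _acceptance_table(params.beta))
    spins.sweep += 1
    return int(flips)


def seed_spins(params: IsingParams) -> SpinLattice:
    """Random spin lattice with equal numbers of +1 and -1 ("infinite temperature")."""
    n = params.width * params.height
    flat = np.full(n, -1, dtype=np.int8)
    flat[: n // 2 + n % 2] = 1
    rng = make_rng(params.seed, "ising-init")
    rng.shuffle(flat)
    return SpinLattice(
        spins=flat.reshape(params.height, params.width), sweep=0, seed=params.seed
    )


def run_ising(
    params: IsingParams,
    n_sweeps: int,
    record_sweeps: Sequence[int] | None = None,
    out_dir: str | Path | None = None,
    initial: SpinLattice | None = None,
) -> tuple[dict[int, SpinLattice], pd.DataFrame]:
    """Run coarsening from a random start; returns snapshots and magnetization.

    ``snapshots`` maps recorded sweep numbers (including 0) to copies of the
    lattice; the DataFrame has one row per sweep with the magnetization m.
    """
    if record_sweeps is None:
        record_sweeps = [n_sweeps]
    record = sorted(set(int(s) for s in record_sweeps))
    if record and (record[0] < 0 or record[-1] > n_sweeps):
        raise ValueError("record sweeps must lie within [0, n_sweeps]")
    state = initial if initial is not None else seed_spins(params)
    rng = make_rng(params.seed, "ising-sweeps")
    snapshots: dict[int, SpinLattice] = {
        0: SpinLattice(state.spins.copy(), 0, params.seed)
    }
    rows = [{"sweep": 0, "m": state.magnetization(), "flips": 0}]
    for t in range(1, n_sweeps + 1):
        flips = sweep(state, params, rng)
        rows.append({"sweep": t, "m": state.magnetization(), "flips": flips})
        if t in record:
            snapshots[t] = SpinLattice(state.spins.copy(), t, params.seed)
    magnetization = pd.DataFrame(rows)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for t, snap in snapshots.items():
            write_snapshot(snap, out / f"snap_{t:06d}")
        magnetization.to_csv(out / "magnetization.csv", index=False)
    return snapshots, magnetization


def run_ising_config(config: RunConfig) -> tuple[dict[int, SpinLattice], pd.DataFrame]:
    """Run from a :class:`RunConfig` with ``model == "ising"``."""
    if config.model != "ising":
        raise ValueError("config.model must be 'ising'")
    params = IsingParams(seed=config.seed, **config.params)
    return run_ising(
        params,
        n_sweeps=int(config.n_steps),
        record_sweeps=[int(s) for s in config.record] or None,
        out_dir=config.out_dir,
    )
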