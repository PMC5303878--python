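"""Inner update loops for the lattice simulators.

Both kernels are written as plain Python functions that consume pre-drawn
random numbers (masks and uniforms generated by a ``numpy.random.Generator``
outside the loop) and are JIT-compiled with numba when it is available.
Because all randomness enters through the arguments, the compiled and
interpreted paths are bit-for-bit identical, and runs are reproducible from
the seed alone.
"""

from __future__ import annotations

import numpy as np

# 8-neighbourhood (Moore) offsets in row-major visit order.
NEIGHBOURS8 = np.array(
    [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)],
    dtype=np.int64,
)


def _ibm_step_impl(grid, alive, killer, repro, choice_u, periodic):
    """One sequential row-major update sweep of the killing/reproduction model.

    grid      : int8 (H, W), entries in {-1, 0, +1}; modified in place
    alive     : bool (H, W), True for cells present at sweep start and not
                yet killed; cells killed earlier in the sweep lose their
                marks, and newborns never act within the sweep
    killer    : bool (H, W), per-cell killer marks for this step
    repro     : bool (H, W), per-cell reproducer marks for this step
    choice_u  : float64 (H, W), uniforms used to pick the empty target patch
    periodic  : bool, wrap neighbour lookups if True
    """
    H, W = grid.shape
    off = NEIGHBOURS8
    for i in range(H):
        for j in range(W):
            if not alive[i, j]:
                continue
            v = grid[i, j]
            if v == 0:
                continue
            if killer[i, j]:
                for k in range(8):
                    ni = i + off[k, 0]
                    nj = j + off[k, 1]
                    if periodic:
                        ni %= H
                        nj %= W
                    elif ni < 0 or ni >= H or nj < 0 or nj >= W:
                        continue
                    if grid[ni, nj] == -v:
                        grid[ni, nj] = 0
                        alive[ni, nj] = False
            if repro[i, j]:
                n_empty = 0
                for k in range(8):
                    ni = i + off[k, 0]
                    nj = j + off[k, 1]
                    if periodic:
                        ni %= H
                        nj %= W
                    elif ni < 0 or ni >= H or nj < 0 or nj >= W:
                        continue
                    if grid[ni, nj] == 0:
                        n_empty += 1
                if n_empty == 0:
                    continue  # reproduction aborted: all neighbours occupied
                target = int(choice_u[i, j] * n_empty)
                if target >= n_empty:  # guard u == 1.0 (cannot occur for [0,1))
                    target = n_empty - 1
                seen = 0
                for k in range(8):
                    ni = i + off[k, 0]
                    nj = j + off[k, 1]
                    if periodic:
                        ni %= H
                        nj %= W
                    elif ni < 0 or ni >= H or nj < 0 or nj >= W:
                        continue
                    if grid[ni, nj] == 0:
                        if seen == target:
                            grid[ni, nj] = v
                            break
                        seen += 1


def _ising_sweep_impl(spins, rows, cols, us, accept):
    """One sweep of random single-spin flip attempts (non-conserved dynamics).

    spins  : int8 (H, W), entries +/-1; modified in place
    rows   : int64 (n,) target row per attempt
    cols   : int64 (n,) target column per attempt
    us     : float64 (n,) uniforms in [0, 1)
    accept : float64 (17,) acceptance weight exp(-2*beta*H) for local
             Hamiltonian H in -8..8 (index H + 8); values above 1 are fine
             since the comparison is `accept > u` with u < 1
    Returns the number of accepted flips.
    """
    H, W = spins.shape
    off = NEIGHBOURS8
    flips = 0
    for n in range(rows.shape[0]):
        i = rows[n]
        j = cols[n]
        s = 0
        for k in range(8):
            s += spins[(i + off[k, 0]) % H, (j + off[k, 1]) % W]
        h = s * spins[i, j]
        if accept[h + 8] > us[n]:
            spins[i, j] = -spins[i, j]
            flips += 1
    return flips


try:  # pragma: no cover - exercised implicitly
    from numba import njit

    ibm_step_kernel = njit(cache=True)(_ibm_step_impl)
    ising_sweep_kernel = njit(cache=True)(_ising_sweep_impl)
    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    ibm_step_kernel = _ibm_step_impl
    ising_sweep_kernel = _ising_sweep_impl
    HAVE_NUMBA = False
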