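"""Deterministic test-pattern generators with known ground-truth statistics.

These synthetic label images stand in for experimental micrographs when
exercising the spatial statistics: each generator's expected structure
factor / assortment behaviour is known in closed form or by direct
enumeration.

* ``random``    — i.i.d. labels; assortment r = 0, flat S(q)
* ``stripes``   — vertical stripes of period ``period``; S(q) peaks at 2*pi/period
* ``checkerboard`` — maximal over-dispersion; non-positive assortment
* ``halves``    — left half one genotype, right half the other; high r at small h
* ``labyrinth`` — thresholded smoothed noise, a stand-in for a coarsened snapshot
* ``labyrinth_scaled`` — block-rescaled copies of one labyrinth, self-similar
  by construction: q_m scales as 1/k and S(q_m) as k^2, so the peak scaling
  exponent is exactly -2
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .core_io import make_rng

__all__ = ["make_pattern", "labyrinth_scaled_series", "PATTERN_KINDS"]

PATTERN_KINDS = ("random", "stripes", "checkerboard", "halves", "labyrinth")


def make_pattern(
    kind: str,
    size: int = 256,
    seed: int = 0,
    freq: float = 0.5,
    period: int = 16,
    smooth: float = 4.0,
) -> np.ndarray:
    """Generate a +/-1 label image of the named kind (size x size)."""
    if size < 8:
        raise ValueError("size must be at least 8")
    if kind == "random":
        rng = make_rng(seed, "fixture-random")
        return np.where(rng.random((size, size)) < freq, 1, -1).astype(np.int8)
    if kind == "stripes":
        if period < 2 or period > size:
            raise ValueError("stripe period must lie in 2..size")
        cols = np.arange(size)
        stripe = np.where((cols % period) < period / 2, 1, -1).astype(np.int8)
        return np.tile(stripe, (size, 1))
    if kind == "checkerboard":
        ii, jj = np.indices((size, size))
        return np.where((ii + jj) % 2 == 0, 1, -1).astype(np.int8)
    if kind == "halves":
        img = np.full((size, size), -1, dtype=np.int8)
        img[:, : size // 2] = 1
        return img
    if kind == "labyrinth":
        rng = make_rng(seed, "fixture-labyrinth")
        noise = rng.standard_normal((size, size))
        smoothed = ndimage.gaussian_filter(noise, sigma=smooth, mode="wrap")
        return np.where(smoothed >= np.median(smoothed), 1, -1).astype(np.int8)
    raise ValueError(f"unknown pattern kind {kind!r}")


def labyrinth_scaled_series(
    size: int = 128, scales: tuple[int, ...] = (1, 2, 4), seed: int = 0, smooth: float = 3.0
) -> tuple[list[np.ndarray], list[float]]:
    """Self-similar image series: one labyrinth magnified by block replication.

    Each scale factor k replicates every pixel of the base pattern into a
    k x k block and crops back to ``size``; domains are therefore exactly k
    times larger, so the peak wavenumber falls as 1/k while the peak height
    grows as k^2 (total spectral weight is fixed by the +/-1 variance while
    it concentrates into 1/k^2 of q-space).  Returns (images, pseudo_times)
    with pseudo-time k^2, matching the t^(1/2) growth law of domain size.
    """
    base = make_pattern("labyrinth", size=size, seed=seed, smooth=smooth)
    images, times = [], []
    for k in scales:
        big = np.kron(base, np.ones((k, k), dtype=np.int8))
        images.append(big[:size, :size])
        times.append(float(k) ** 2)
    return images, times
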