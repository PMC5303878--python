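"""Reaction-diffusion model of two mutually killing strains, with public goods.

Two strains share a basal growth rate ``r`` and density-dependent mortality
``s`` and kill each other on contact: strain A kills B at rate ``alpha_ba``
and B kills A at rate ``alpha_ab``.  With cell dispersal ``d`` the densities
obey

    dA/dt = A (r - s (A + B) - alpha_ab B) + d lap A
    dB/dt = B (r - s (A + B) - alpha_ba A) + d lap B

The public-goods extension makes strain A a cooperator that secretes a
diffusible good S at rate ``rho`` and pays a growth-rate cost ``c``; the
good decays at rate ``lam``, diffuses with coefficient ``D`` and raises both
strains' growth rate by ``b`` per unit concentration:

    dA/dt = A (r - c + b S - s (A + B) - alpha B) + d lap A
    dB/dt = B (r + b S - s (A + B) - alpha A) + d lap B
    dS/dt = rho A - lam S + D lap S

Time stepping is explicit forward Euler on a periodic grid with a checked
diffusive stability bound; the stiff decay/production part of the good
equation is handled by an exact exponential substep so that a fast-decaying
good (lam = 100 in the default set) does not dictate the time step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import FieldState, make_rng

__all__ = [
    "TwoStrainParams",
    "PublicGoodsParams",
    "Perturbation",
    "laplacian",
    "rhs_two_strain",
    "rhs_public_goods",
    "integrate",
    "perturbation_growth",
    "run_cooperation_scenarios",
]


@dataclass
class TwoStrainParams:
    """Rates of the two-strain killing model (defaults: the standard set
    r=2, s=2, alpha_ab=alpha_ba=0.5, d=0.01)."""

    r: float = 2.0
    s: float = 2.0
    alpha_ab: float = 0.5  # rate at which B kills A
    alpha_ba: float = 0.5  # rate at which A kills B
    d: float = 0.01

    def __post_init__(self) -> None:
        for name in ("r", "s", "alpha_ab", "alpha_ba", "d"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class PublicGoodsParams:
    """Rates of the cooperator/cheat model with symmetric killing ``alpha``.

    ``s > rho*b/lam`` is required so that a pure cooperator population has a
    finite stable equilibrium.  Defaults are the standard set r=2, s=2,
    alpha=0.5, b=1.9, c=0.1, rho=lam=100, D=0.1, d=0.01.
    """

    r: float = 2.0
    s: float = 2.0
    alpha: float = 0.5
    b: float = 1.9
    c: float = 0.1
    rho: float = 100.0
    lam: float = 100.0
    D: float = 0.1
    d: float = 0.01

    def __post_init__(self) -> None:
        for name in ("r", "s", "alpha", "b", "c", "rho", "lam", "D", "d"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.lam <= 0:
            raise ValueError("lam must be positive")
        if not self.s > self.rho * self.b / self.lam:
            raise ValueError(
                "require s > rho*b/lam for a finite cooperator equilibrium"
            )


@dataclass
class Perturbation:
    """Sinusoidal compositional fluctuation a*sin(beta_wave * x)."""

    a: float
    beta_wave: float

    def __post_init__(self) -> None:
        if self.a < 0:
            raise ValueError("amplitude a must be non-negative")
        if self.beta_wave <= 0:
            raise ValueError("beta_wave must be positive")


def laplacian(f: np.ndarray, dx: float) -> np.ndarray:
    """Second-order finite-difference Laplacian on a periodic grid (1-D or 2-D)."""
    out = -2.0 * f.ndim * f
    for axis in range(f.ndim):
        out += np.roll(f, 1, axis=axis) + np.roll(f, -1, axis=axis)
    return out / dx**2


def rhs_two_strain(state: FieldState, params: TwoStrainParams) -> tuple[np.ndarray, np.ndarray]:
    """Time derivatives (dA/dt, dB/dt) of the two-strain killing model."""
    A, B = state.A, state.B
    if A.shape != B.shape:
        raise ValueError("field shapes do not match")
    total = A + B
    dA = A * (params.r - params.s * total - params.alpha_ab * B) + params.d * laplacian(A, state.dx)
    dB = B * (params.r - params.s * total - params.alpha_ba * A) + params.d * laplacian(B, state.dx)
    return dA, dB


def rhs_public_goods(
    state: FieldState, params: PublicGoodsParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Time derivatives (dA/dt, dB/dt, dS/dt) of the cooperator/cheat model."""
    if state.S is None:
        raise ValueError("public-goods dynamics require an S field")
    A, B, S = state.A, state.B, state.S
    total = A + B
    growth = params.r + params.b * S - params.s * total
    dA = A * (growth - params.c - params.alpha * B) + params.d * laplacian(A, state.dx)
    dB = B * (growth - params.alpha * A) + params.d * laplacian(B, state.dx)
    dS = params.rho * A - params.lam * S + params.D * laplacian(S, state.dx)
    return dA, dB, dS


def coexistence_densities(params: TwoStrainParams) -> tuple[float, float]:
    """Uniform coexistence densities of the two-strain model.

    A* = alpha_ab r / (s(alpha_ab+alpha_ba) + alpha_ab alpha_ba) and
    symmetrically for B*; for alpha_ab = alpha_ba = 0 the (degenerate)
    symmetric point r/(2s) is returned.
    """
    aab, aba = params.alpha_ab, params.alpha_ba
    denom = params.s * (aab + aba) + aab * aba
    if denom == 0:
        half = params.r / (2 * params.s)
        return half, half
    return aab * params.r / denom, aba * params.r / denom


def _check_dt(dt: float, dx: float, params: TwoStrainParams | PublicGoodsParams) -> None:
    dmax = params.d
    if isinstance(params, PublicGoodsParams):
        dmax = max(dmax, params.D)
    if dmax > 0:
        bound = dx**2 / (4.0 * dmax)
        if dt >= bound:
            raise ValueError(
                f"dt={dt} violates the diffusive stability bound dt < dx^2/(4 max(d,D)) = {bound:g}"
            )


def integrate(
    state: FieldState,
    params: TwoStrainParams | PublicGoodsParams,
    t_end: float,
    dt: float,
    record_times: Sequence[float] = (),
    split_good: bool = True,
) -> list[FieldState]:
    """Forward-Euler integration on a periodic grid.

    Returns the recorded snapshots (times rounded to whole steps), always
    including the final state.  Negative densities produced by an Euler
    undershoot are clipped to zero; the cumulative number of clipped entries
    is stored in each snapshot's ``meta["clip_events"]`` and a warning is
    emitted if any occurred.  With ``split_good`` (default) the production
    and decay of the good are integrated exactly over each step, so ``dt``
    is limited by the ecological rates and the diffusive bound only.
    """
    _check_dt(dt, state.dx, params)
    goods = isinstance(params, PublicGoodsParams)
    if goods and state.S is None:
        raise ValueError("public-goods dynamics require an S field")
    st = state.copy()
    n_steps = int(round(t_end / dt))
    record = sorted(set(int(round(t / dt)) for t in record_times))
    if record and (record[0] < 0 or record[-1] > n_steps):
        raise ValueError("record times must lie within [0, t_end]")
    out: list[FieldState] = []
    clip_events = 0
    decay = np.exp(-params.lam * dt) if goods else 0.0

    def snap(step: int) -> FieldState:
        s = st.copy()
        s.t = step * dt
        s.meta["clip_events"] = clip_events
        return s

    if 0 in record:
        out.append(snap(0))
    for step in range(1, n_steps + 1):
        if goods:
            dA, dB, _ = rhs_public_goods(st, params)
            # exact integration of dS/dt = F - lam*S with F frozen over the step
            F = params.rho * st.A + params.D * laplacian(st.S, st.dx)
            st.S = st.S * decay + (F / params.lam) * (1.0 - decay)
        else:
            dA, dB = rhs_two_strain(st, params)
        st.A = st.A + dt * dA
        st.B = st.B + dt * dB
        for name in ("A", "B", "S"):
            f = getattr(st, name)
            if f is None:
                continue
            neg = f < 0
            n_neg = int(np.count_nonzero(neg))
            if n_neg:
                clip_events += n_neg
                f[neg] = 0.0
        if step % 200 == 0 or step == n_steps:
            if not np.isfinite(st.A).all() or not np.isfinite(st.B).all():
                raise FloatingPointError(f"non-finite field at step {step} (t={step * dt:g})")
        if step in record or step == n_steps:
            out.append(snap(step))
    if clip_events:
        warnings.warn(
            f"clipped {clip_events} negative field entries during integration",
            RuntimeWarning,
            stacklevel=2,
        )
    return out


def _sine_mode_amplitude(phi: np.ndarray, x: np.ndarray, beta: float) -> float:
    """Amplitude of the sin(beta x) mode of a 1-D profile (L2 projection)."""
    basis = np.sin(beta * x)
    return float(2.0 * np.mean((phi - phi.mean()) * basis))


def perturbation_growth(
    params: TwoStrainParams | PublicGoodsParams,
    pert: Perturbation,
    horizon: float = 1.0,
    n_cells: int = 1024,
    n_wavelengths: int = 4,
    length: float | None = None,
    dt: float | None = None,
    base_state: tuple[float, float] | None = None,
) -> float:
    """Exponential growth rate of a sinusoidal composition mode.

    A 1-D periodic domain commensurate with the wavelength 2*pi/beta is
    initialised at the uniform coexistence state plus a compositional
    fluctuation +a*sin(beta x) in A and -a*sin(beta x) in B, integrated over
    ``horizon`` time units, and the slope of log|amplitude| of the sin mode
    of phi_A = A/(A+B) against time is returned (negative means the mode
    decays).  The linearised expectation for the symmetric two-strain model
    is ``alpha*A0 - d*beta^2``.
    """
    wavelength = 2 * np.pi / pert.beta_wave
    if length is None:
        length = n_wavelengths * wavelength
    n_waves = length / wavelength
    if abs(n_waves - round(n_waves)) > 1e-9 * max(1.0, n_waves):
        raise ValueError(
            f"domain length {length:g} is not an integer multiple of the wavelength "
            f"2*pi/beta = {wavelength:g} (mode leakage)"
        )
    dx = length / n_cells
    x = np.arange(n_cells) * dx
    if base_state is not None:
        A0, B0 = base_state
    elif isinstance(params, PublicGoodsParams):
        from .wellmixed import cooperator_equilibria

        interior = [e for e in cooperator_equilibria(params) if min(e.point[:2]) > 0]
        if not interior:
            raise ValueError("no interior coexistence state to perturb (alpha below threshold)")
        A0, B0 = interior[0].point[:2]
    else:
        A0, B0 = coexistence_densities(params)
    if pert.a > 0.01 * min(A0, B0) * 1.0000001:
        warnings.warn(
            "perturbation amplitude exceeds 1% of the base density; "
            "growth-rate fit may pick up nonlinear terms",
            RuntimeWarning,
            stacklevel=2,
        )
    mode = pert.a * np.sin(pert.beta_wave * x)
    A = A0 + mode
    B = B0 - mode
    if isinstance(params, PublicGoodsParams):
        S = params.rho / params.lam * A  # quasi-steady start
        state = FieldState(A=A, B=np.clip(B, 0, None), S=S, dx=dx)
    else:
        state = FieldState(A=A, B=np.clip(B, 0, None), dx=dx)
    if dt is None:
        bound = dx**2 / (4.0 * max(params.d, getattr(params, "D", 0.0), 1e-300))
        dt = min(1e-2, 0.5 * bound, horizon / 20)
    times = np.linspace(0, horizon, 16)[1:]
    traj = integrate(state, params, t_end=horizon, dt=dt, record_times=times)
    ts, amps = [], []
    for snap in traj:
        amp = _sine_mode_amplitude(snap.composition(), x, pert.beta_wave)
        if amp > 0:
            ts.append(snap.t)
            amps.append(amp)
    if len(ts) < 3:
        raise RuntimeError("composition mode vanished before a rate could be fitted")
    fit = stats.linregress(ts, np.log(amps))
    return float(fit.slope)


def _binary_spatial_state(
    params: PublicGoodsParams,
    freq_A: float,
    n_cells: int,
    dx: float,
    seed: int,
) -> FieldState:
    """Random genotype assignment per grid cell, mirroring a randomly seeded lattice.

    Each cell starts at the cheat single-strain density r/s and is assigned
    to the cooperator with probability ``freq_A``; the good starts at its
    local quasi-steady value.
    """
    rng = make_rng(seed, "pde-scenario-init")
    dens = params.r / params.s
    is_coop = rng.random(n_cells) < freq_A
    A = np.where(is_coop, dens, 0.0)
    B = np.where(is_coop, 0.0, dens)
    S = params.rho / params.lam * A
    return FieldState(A=A, B=B, S=S, dx=dx)


def run_cooperation_scenarios(
    params: PublicGoodsParams,
    init_freqs: Sequence[float],
    spatial: bool,
    killing: bool,
    t_end: float | None = None,
    n_cells: int = 1024,
    dx: float = 0.1,
    dt: float = 0.002,
    n_record: int = 60,
    seed: int = 0,
) -> pd.DataFrame:
    """Global cooperator frequency through time for one model scenario.

    The four scenarios (spatial x killing) contrast the fate of a public-good
    producer against a cheat.  ``killing=False`` runs with alpha = 0.
    Non-spatial runs integrate the well-mixed three-variable ODE from a
    mixed state at total density r/s; spatial runs use a 1-D periodic domain
    seeded with a random per-cell genotype assignment (small-scale spatial
    noise from which phase separation can nucleate).  Returns a long-format
    DataFrame with columns (scenario, f0, t, freq_coop).
    """
    from .wellmixed import integrate_wellmixed

    p = params if killing else replace(params, alpha=0.0)
    if t_end is None:
        t_end = 600.0 if spatial else 200.0
    rows = []
    label = f"{'spatial' if spatial else 'nonspatial'}_{'killing' if killing else 'nokill'}"
    for f0 in init_freqs:
        if not 0 < f0 < 1:
            raise ValueError("initial frequencies must lie in (0, 1)")
        if spatial:
            state = _binary_spatial_state(p, f0, n_cells, dx, seed)
            record = np.linspace(0, t_end, n_record)[1:]
            traj = integrate(state, p, t_end=t_end, dt=dt, record_times=record)
            for snap in [state] + traj:
                tot_A = float(snap.A.mean())
                tot_B = float(snap.B.mean())
                rows.append(
                    {
                        "scenario": label,
                        "f0": f0,
                        "t": snap.t,
                        "freq_coop": tot_A / (tot_A + tot_B),
                    }
                )
        else:
            dens = p.r / p.s
            y0 = (f0 * dens, (1 - f0) * dens, p.rho / p.lam * f0 * dens)
            tr = integrate_wellmixed(y0, p, t_end=t_end, n_eval=n_record)
            for _, row in tr.iterrows():
                tot = row["A"] + row["B"]
                rows.append(
                    {
                        "scenario": label,
                        "f0": f0,
                        "t": row["t"],
                        "freq_coop": row["A"] / tot if tot > 0 else np.nan,
                    }
                )
    return pd.DataFrame(rows)
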