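"""Analytic results for the non-spatial (well-mixed) models.

For the two-strain killing ODE

    dA/dt = A (r - s (A + B) - alpha_ab B)
    dB/dt = B (r - s (A + B) - alpha_ba A)

there are exactly four equilibria: the bacteria-free state (0, 0)
(unstable for r > 0), the two single-strain states (r/s, 0) and (0, r/s)
(stable whenever the resident is killed back, alpha > 0), and a coexistence
state

    A* = alpha_ab r / (s (alpha_ab + alpha_ba) + alpha_ab alpha_ba),
    B* = alpha_ba r / (s (alpha_ab + alpha_ba) + alpha_ab alpha_ba),

which is a saddle, so one strain always comes to dominate.  The coexistence
ratio A*/B* = alpha_ab/alpha_ba is also the separatrix: A wins from
(A0, B0) iff A0/B0 > alpha_ab/alpha_ba.

For the cooperator/cheat model the public good is taken at quasi-steady
state, S = rho*A/lam (the good equilibrates much faster than the ecology),
which gives a planar system with a pure-cooperator equilibrium
A* = lam (r - c)/(lam s - rho b) that is stable iff

    alpha > c (lam s - rho b) / (lam (r - c)),

an always-stable pure-cheat equilibrium B* = r/s, and, above that killing
threshold, an interior saddle with A-coordinate exceeding its B-coordinate
whenever c > 0 (the cooperator's basin of attraction is the smaller one).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .pde import PublicGoodsParams, TwoStrainParams

__all__ = [
    "EquilibriumReport",
    "jacobian_two_strain",
    "equilibria_two_strain",
    "domination_outcome",
    "alpha_critical",
    "cooperator_equilibria",
    "integrate_wellmixed",
    "fitness_difference",
]

_EIG_TOL = 1e-9


@dataclass
class EquilibriumReport:
    """One equilibrium with its Jacobian trace/determinant and classification."""

    point: tuple[float, ...]
    trace: float
    det: float
    classification: str  # stable | unstable | saddle | degenerate
    eigenvalues: tuple[float, ...] = ()
    residual: float = 0.0


def _classify(J: np.ndarray) -> tuple[str, tuple[float, ...]]:
    eig = np.linalg.eigvals(J)
    re = np.sort(np.real(eig))
    if re[-1] < -_EIG_TOL:
        cls = "stable"
    elif re[0] > _EIG_TOL:
        cls = "unstable"
    elif re[0] < -_EIG_TOL < _EIG_TOL < re[-1]:
        cls = "saddle"
    else:
        cls = "degenerate"
    return cls, tuple(float(x) for x in re)


def _rhs_two(A: float, B: float, p: TwoStrainParams) -> tuple[float, float]:
    total = A + B
    return (
        A * (p.r - p.s * total - p.alpha_ab * B),
        B * (p.r - p.s * total - p.alpha_ba * A),
    )


def jacobian_two_strain(A: float, B: float, p: TwoStrainParams) -> np.ndarray:
    """Jacobian of the two-strain killing ODE at (A, B)."""
    return np.array(
        [
            [p.r - p.s * (2 * A + B) - p.alpha_ab * B, -A * (p.s + p.alpha_ab)],
            [-B * (p.s + p.alpha_ba), p.r - p.s * (A + 2 * B) - p.alpha_ba * A],
        ]
    )


def _report_two(A: float, B: float, p: TwoStrainParams) -> EquilibriumReport:
    J = jacobian_two_strain(A, B, p)
    cls, eig = _classify(J)
    fa, fb = _rhs_two(A, B, p)
    return EquilibriumReport(
        point=(A, B),
        trace=float(np.trace(J)),
        det=float(np.linalg.det(J)),
        classification=cls,
        eigenvalues=eig,
        residual=max(abs(fa), abs(fb)),
    )


def equilibria_two_strain(p: TwoStrainParams) -> list[EquilibriumReport]:
    """The four equilibria of the two-strain model, classified.

    Order: bacteria-free, A-only, B-only, coexistence.  With both killing
    rates zero the "coexistence" point degenerates onto the neutral line
    A + B = r/s and is reported as degenerate.
    """
    if p.s == 0:
        raise ValueError("s = 0: single-strain equilibrium r/s undefined")
    if p.r <= 0:
        raise ValueError("require r > 0")
    reports = [
        _report_two(0.0, 0.0, p),
        _report_two(p.r / p.s, 0.0, p),
        _report_two(0.0, p.r / p.s, p),
    ]
    denom = p.s * (p.alpha_ab + p.alpha_ba) + p.alpha_ab * p.alpha_ba
    if denom > 0:
        reports.append(
            _report_two(p.alpha_ab * p.r / denom, p.alpha_ba * p.r / denom, p)
        )
    else:
        reports.append(_report_two(p.r / (2 * p.s), p.r / (2 * p.s), p))
    return reports


def domination_outcome(A0: float, B0: float, p: TwoStrainParams) -> str:
    """Which strain fixes from (A0, B0): "A", "B" or "separatrix".

    A dominates iff A0/B0 > alpha_ab/alpha_ba, i.e. iff the initial ratio
    lies on the A side of the saddle's stable manifold (a straight ray for
    this system).
    """
    if A0 <= 0 or B0 <= 0:
        raise ValueError("initial densities must be positive")
    lhs = A0 * p.alpha_ba
    rhs = B0 * p.alpha_ab
    if np.isclose(lhs, rhs, rtol=1e-12, atol=0.0):
        return "separatrix"
    return "A" if lhs > rhs else "B"


def alpha_critical(p: PublicGoodsParams) -> float:
    """Killing rate above which the pure-cooperator equilibrium is stable:
    alpha_crit = c (lam s - rho b) / (lam (r - c))."""
    if p.r <= p.c:
        raise ValueError("require r > c for a viable cooperator")
    return p.c * (p.lam * p.s - p.rho * p.b) / (p.lam * (p.r - p.c))


def _qss_rhs(A: float, B: float, p: PublicGoodsParams) -> tuple[float, float]:
    # S eliminated at quasi-steady state S = rho*A/lam
    bS = p.b * p.rho * A / p.lam
    total = A + B
    return (
        A * (p.r - p.c + bS - p.s * total - p.alpha * B),
        B * (p.r + bS - p.s * total - p.alpha * A),
    )


def _qss_jacobian(A: float, B: float, p: PublicGoodsParams) -> np.ndarray:
    k = p.b * p.rho / p.lam
    gA = p.r - p.c + k * A - p.s * (A + B) - p.alpha * B
    gB = p.r + k * A - p.s * (A + B) - p.alpha * A
    return np.array(
        [
            [gA + A * (k - p.s), A * (-p.s - p.alpha)],
            [B * (k - p.s - p.alpha), gB - p.s * B],
        ]
    )


def _report_goods(A: float, B: float, p: PublicGoodsParams) -> EquilibriumReport:
    J = _qss_jacobian(A, B, p)
    cls, eig = _classify(J)
    fa, fb = _qss_rhs(A, B, p)
    return EquilibriumReport(
        point=(A, B, p.rho * A / p.lam),
        trace=float(np.trace(J)),
        det=float(np.linalg.det(J)),
        classification=cls,
        eigenvalues=eig,
        residual=max(abs(fa), abs(fb)),
    )


def cooperator_equilibria(p: PublicGoodsParams) -> list[EquilibriumReport]:
    """Pure-cooperator, pure-cheat and (if present) interior saddle equilibria.

    Points are reported as (A, B, S) with the quasi-steady good S = rho*A/lam.
    The interior point exists iff alpha > alpha_critical(p); it satisfies
    A - B = c/alpha and its A-coordinate exceeds its B-coordinate whenever
    the cost of cooperation is positive.
    """
    if not p.s > p.rho * p.b / p.lam:
        raise ValueError("invariant violated: require s > rho*b/lam")
    if p.r <= p.c:
        raise ValueError("require r > c for a viable cooperator")
    A_coop = p.lam * (p.r - p.c) / (p.lam * p.s - p.rho * p.b)
    reports = [
        _report_goods(A_coop, 0.0, p),
        _report_goods(0.0, p.r / p.s, p),
    ]
    if p.alpha > 0 and p.alpha > alpha_critical(p):
        A_sad = (p.r + p.s * p.c / p.alpha) / (2 * p.s + p.alpha - p.b * p.rho / p.lam)
        B_sad = A_sad - p.c / p.alpha
        if B_sad > 0:
            reports.append(_report_goods(A_sad, B_sad, p))
    return reports


def _full_rhs(t, y, p: TwoStrainParams | PublicGoodsParams):
    if isinstance(p, PublicGoodsParams):
        A, B, S = y
        total = A + B
        growth = p.r + p.b * S - p.s * total
        return [
            A * (growth - p.c - p.alpha * B),
            B * (growth - p.alpha * A),
            p.rho * A - p.lam * S,
        ]
    A, B = y
    fa, fb = _rhs_two(A, B, p)
    return [fa, fb]


def integrate_wellmixed(
    y0: Sequence[float],
    p: TwoStrainParams | PublicGoodsParams,
    t_end: float,
    n_eval: int = 200,
) -> pd.DataFrame:
    """Adaptive integration of the 2- or 3-variable well-mixed system.

    Uses LSODA (the good equation is stiff at lam = 100).  Returns a
    DataFrame with columns t, A, B (and S for the public-goods model);
    tiny negative excursions from the solver are clipped to zero.
    """
    if any(v < 0 for v in y0):
        raise ValueError("initial densities must be non-negative")
    n_var = 3 if isinstance(p, PublicGoodsParams) else 2
    if len(y0) != n_var:
        raise ValueError(f"expected {n_var} initial values, got {len(y0)}")
    t_eval = np.linspace(0.0, t_end, n_eval)
    sol = solve_ivp(
        _full_rhs,
        (0.0, t_end),
        np.asarray(y0, dtype=float),
        args=(p,),
        method="LSODA",
        t_eval=t_eval,
        rtol=1e-9,
        atol=1e-12,
    )
    if not sol.success:  # pragma: no cover
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    y = np.clip(sol.y, 0.0, None)
    cols = {"t": sol.t, "A": y[0], "B": y[1]}
    if n_var == 3:
        cols["S"] = y[2]
    return pd.DataFrame(cols)


def fitness_difference(A: float, B: float, p: PublicGoodsParams) -> float:
    """Per-capita growth advantage of the cooperator, w_A - w_B = -c + alpha (A - B).

    Under the quasi-steady good both strains share the r + b S - s (A+B)
    terms, so the advantage reduces to the production cost against the
    killing asymmetry; its sign flips with A - B at fixed total density
    (positive frequency dependence induced by killing).
    """
    return -p.c + p.alpha * (A - B)
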