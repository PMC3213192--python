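"""Continuum (rate-equation) description of the cytosolic density.

Treating the cytosolic density ``rho_c`` as a continuous variable and
rescaling time by ``k_off`` (``tau = k_off * t``), the circuit reduces
to a single ODE with a quadratic right-hand side:

    d rho_c / d tau = (rho_T - rho_c) * (1 - rho_c / rho_star)
                      - alpha * rho_c

With no spontaneous activation (``alpha = 0``) the two equilibria are
``rho_T`` and ``rho_star``; the smaller is stable and stability is
exchanged exactly at ``rho_T = rho_star`` — a transcritical
bifurcation.  For ``alpha > 0`` the crossing is smoothed (imperfect
transcritical): the quadratic has two real roots, the larger always
exceeds ``rho_T`` and is unphysical, and the unique physical
equilibrium is stable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .model_core import DerivedConstants, ModelParams, derive_constants

__all__ = [
    "SteadyStateResult",
    "DegenerateRootError",
    "cytosol_rate",
    "steady_states",
    "integrate_density",
    "bifurcation_scan",
]

#: roots closer than this (relative to rho_star) are reported degenerate
DOUBLE_ROOT_RTOL = 1e-9


class DegenerateRootError(ValueError):
    """The two equilibria coincide (rho_T = rho_star at alpha = 0)."""


@dataclass(frozen=True)
class SteadyStateResult:
    roots: tuple
    stability: tuple       # per-root: "stable" | "unstable"
    physical: tuple        # per-root: root in [0, rho_T]
    bifurcation_type: str  # "transcritical" | "imperfect_transcritical" | "none"

    @property
    def stable_root(self) -> float:
        return self.roots[self.stability.index("stable")]


def cytosol_rate(rho_c: float, consts: DerivedConstants) -> float:
    """d rho_c / d tau of the rescaled rate equation (tau = k_off * t)."""
    return (consts.rho_T - rho_c) * (1.0 - rho_c / consts.rho_star) \
        - consts.alpha_on_off * rho_c


def steady_states(consts: DerivedConstants) -> SteadyStateResult:
    """Equilibria of the rate equation with stability and physicality.

    Solves ``rho^2 - b*rho + rho_T*rho_star = 0`` where
    ``b = rho_T + rho_star*(1 + alpha)`` using the cancellation-free
    form ``rho_small = 2*rho_T*rho_star / (b + sqrt(disc))``, which
    stays accurate near the transcritical point where the naive
    ``(b - sqrt(disc))/2`` loses all significant digits.
    """
    rho_T, rho_s, alpha = consts.rho_T, consts.rho_star, consts.alpha_on_off
    if alpha == 0.0:
        if abs(rho_T - rho_s) <= DOUBLE_ROOT_RTOL * rho_s:
            raise DegenerateRootError(
                f"degenerate double root: rho_T = rho_star = {rho_s!r} at alpha = 0"
            )
        lo, hi = sorted((rho_T, rho_s))
        return SteadyStateResult(
            roots=(lo, hi),
            stability=("stable", "unstable"),
            physical=(lo <= rho_T, hi <= rho_T),
            bifurcation_type="transcritical",
        )
    b = rho_T + rho_s * (1.0 + alpha)
    # disc = (rho_T - rho_s)^2 + 2*alpha*rho_s*(rho_T + rho_s) + (alpha*rho_s)^2 > 0
    disc = b * b - 4.0 * rho_T * rho_s
    sq = np.sqrt(disc)
    lo = 2.0 * rho_T * rho_s / (b + sq)
    hi = 0.5 * (b + sq)
    if hi - lo <= DOUBLE_ROOT_RTOL * rho_s:
        raise DegenerateRootError("degenerate double root at alpha > 0")
    return SteadyStateResult(
        roots=(lo, hi),
        stability=("stable", "unstable"),
        physical=(lo <= rho_T * (1 + 1e-12), hi <= rho_T * (1 + 1e-12)),
        bifurcation_type="imperfect_transcritical",
    )


def integrate_density(
    rho0: float,
    consts: DerivedConstants,
    t_end: float,
    k_off: float = 9.0,
    n_points: int = 200,
    rtol: float = 1e-9,
    atol: float = 1e-12,
):
    """Integrate the rate equation from ``rho0`` for ``t_end`` minutes.

    Returns ``(t_minutes, rho_c)`` arrays.  Integration is performed in
    rescaled time and un-rescaled on output.  A solver failure raises
    rather than silently clipping the trajectory.
    """
    if not (0.0 <= rho0 <= consts.rho_T * (1 + 1e-12)):
        raise ValueError(f"rho0 = {rho0} outside [0, rho_T = {consts.rho_T}]")
    tau_end = k_off * t_end
    sol = solve_ivp(
        lambda _t, y: cytosol_rate(y[0], consts),
        (0.0, tau_end),
        [rho0],
        t_eval=np.linspace(0.0, tau_end, n_points),
        rtol=rtol,
        atol=atol,
        method="LSODA",
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    rho = sol.y[0]
    # the flow preserves [0, rho_T]; tolerate solver-level rounding only
    if rho.min() < -1e-9 or rho.max() > consts.rho_T * (1 + 1e-6) + 1e-9:
        raise RuntimeError("trajectory left the physical interval [0, rho_T]")
    return sol.t / k_off, np.clip(rho, 0.0, consts.rho_T)


def bifurcation_scan(
    params_template: ModelParams,
    rho_T_grid: Sequence[float],
) -> pd.DataFrame:
    """Equilibrium branch table over a grid of total densities.

    For each ``rho_T`` in the (strictly increasing) grid, reports both
    roots, their stability, and the equilibrium membrane fraction
    ``f = max(0, 1 - rho_c_stable / rho_T)``.  A degenerate grid point
    (exactly at the transcritical point with alpha = 0) is reported
    with the double root marked ``degenerate``.
    """
    grid = np.asarray(rho_T_grid, dtype=float)
    if grid.ndim != 1 or len(grid) < 1 or np.any(np.diff(grid) <= 0):
        raise ValueError("rho_T_grid must be 1-D and strictly increasing")
    base = derive_constants(params_template)
    rows = []
    for rho_T in grid:
        consts = DerivedConstants(
            rho_T=rho_T,
            rho_star=base.rho_star,
            alpha_on_off=base.alpha_on_off,
            beta_on_fb=base.beta_on_fb,
            R0=rho_T / base.rho_star,
            N_star=base.N_star,
        )
        try:
            res = steady_states(consts)
            stable = res.stable_root
            rows.append(
                dict(
                    rho_T=rho_T,
                    root_low=res.roots[0],
                    root_high=res.roots[1],
                    stability_low=res.stability[0],
                    stability_high=res.stability[1],
                    membrane_fraction=max(0.0, 1.0 - stable / rho_T) if rho_T > 0 else 0.0,
                )
            )
        except DegenerateRootError:
            rows.append(
                dict(
                    rho_T=rho_T,
                    root_low=rho_T,
                    root_high=rho_T,
                    stability_low="degenerate",
                    stability_high="degenerate",
                    membrane_fraction=0.0,
                )
            )
    return pd.DataFrame(rows)
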