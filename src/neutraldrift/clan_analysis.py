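"""Genealogy statistics over clan labels.

Between spontaneous on-events the membrane population evolves as a
neutral multi-type birth-death process: every molecule recruits and
dissociates at equal per-capita rates regardless of its clan, so clan
sizes drift with no systematic bias and extinction is permanent.  The
consequence is consolidation: starting from ``K`` clans, half are
expected to be gone after

    T_half = N_m / (K * lambda)

and a single clan is expected to remain after

    T_single = (1 - 1/K) * N_m / lambda

where ``N_m`` is the standing membrane population and
``lambda = (k_off + k_fb*(V_fb/V)*N_c) / 2`` the per-capita turnover
rate (equal to ``k_off`` at quasi-steady state, where recruitment
balances dissociation).  These are the neutral-coalescent timescales
of the embedded Moran-type dynamics (pairwise lineage coalescence at
rate ``2*lambda/N_m``) and are self-consistent: the time to go from
``K`` to ``K/2`` clans equals ``T_single(K) - T_single(K/2)
= N_m/(K*lambda)``, and ``T_half(K=2) = T_single(K=2)`` exactly.
Both are expectations over a wide-variance process, validated against
simulation medians rather than asserted tightly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model_core import ModelParams
from .membrane_sim import ParticleState, Trajectory

__all__ = [
    "ClanStats",
    "clan_trajectory",
    "clan_half_life",
    "single_clan_time",
    "winner_locality",
    "circular_spread",
]


@dataclass(frozen=True)
class ClanStats:
    times: np.ndarray
    n_surviving: np.ndarray
    K: int
    winner_id: int | None
    t_half_hat: float | None     # first time n_surviving <= ceil(K/2)
    t_single_hat: float | None   # first time n_surviving == 1
    winner_spread: float | None  # circular spread at consolidation


def circular_spread(positions: np.ndarray, L: float) -> float:
    """Circular standard deviation of angular positions, in length
    units (sqrt(-2 ln R) * L / 2pi with R the mean resultant length)."""
    if len(positions) == 0:
        raise ValueError("no positions")
    theta = positions / L * 2.0 * np.pi
    R = abs(np.mean(np.exp(1j * theta)))
    R = min(max(R, 1e-300), 1.0)
    return float(np.sqrt(-2.0 * np.log(R)) * L / (2.0 * np.pi))


def clan_trajectory(traj: Trajectory) -> ClanStats:
    """Surviving-clan counts and crossing times of a recorded run.

    ``K`` is the clan count of the first record.  The winner is defined
    only if exactly one clan remains at the end with a nonempty
    membrane; the spread is evaluated at the first single-clan record.
    """
    if traj.clan_ids is None:
        raise ValueError("trajectory was recorded without clan labels")
    n_surv = np.array([len(np.unique(c)) for c in traj.clan_ids])
    K = int(n_surv[0])
    half_level = math.ceil(K / 2)
    t_half = None
    t_single = None
    spread = None
    winner = None
    idx_half = np.nonzero(n_surv <= half_level)[0]
    # require a nonempty membrane: an empty membrane has 0 clans
    idx_half = idx_half[np.array([len(traj.clan_ids[i]) > 0 for i in idx_half])]
    if len(idx_half):
        t_half = float(traj.times[idx_half[0]])
    idx_single = np.nonzero(n_surv == 1)[0]
    if len(idx_single):
        i0 = int(idx_single[0])
        t_single = float(traj.times[i0])
        spread = circular_spread(traj.positions[i0], traj.L)
    if len(traj.clan_ids[-1]) and len(np.unique(traj.clan_ids[-1])) == 1:
        winner = int(traj.clan_ids[-1][0])
    return ClanStats(
        times=traj.times,
        n_surviving=n_surv,
        K=K,
        winner_id=winner,
        t_half_hat=t_half,
        t_single_hat=t_single,
        winner_spread=spread,
    )


def _turnover_rate(params: ModelParams, N_m: int) -> float:
    """Per-capita turnover (birth+death)/2 of a membrane molecule at
    cytosolic count N_T - N_m."""
    n_c = params.N_T - N_m
    return 0.5 * (params.k_off + params.k_fb * (params.V_fb / params.V) * n_c)


def clan_half_life(params: ModelParams, K: int, N_m: int) -> float:
    """Expected time (minutes) until half the initial clans are extinct."""
    if K < 2:
        raise ValueError("K must be >= 2")
    if N_m < 1:
        raise ValueError("N_m must be >= 1")
    lam = _turnover_rate(params, N_m)
    if lam == 0:
        return math.inf
    return N_m / (K * lam)


def single_clan_time(params: ModelParams, K: int, N_m: int) -> float:
    """Expected time (minutes) until only one clan remains."""
    if K < 2:
        raise ValueError("K must be >= 2")
    if N_m < 1:
        raise ValueError("N_m must be >= 1")
    lam = _turnover_rate(params, N_m)
    if lam == 0:
        return math.inf
    return (1.0 - 1.0 / K) * N_m / lam


def winner_locality(state: ParticleState, params: ModelParams) -> float:
    """Circular spread of the single surviving clan's positions.

    Raises if more than one clan survives (the quantity is undefined
    before consolidation) or the membrane is empty.
    """
    if state.N_m == 0:
        raise ValueError("membrane is empty: no winner")
    if len(np.unique(state.clan_ids)) != 1:
        raise ValueError("more than one clan survives: winner undefined")
    return circular_spread(state.positions, params.L)
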