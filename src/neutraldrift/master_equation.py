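"""Exact stochastic treatment of the cytosolic molecule count.

The number of cytosolic molecules ``n`` performs a one-step (birth-
death) continuous-time Markov chain on ``{0, ..., N_T}``:

* birth ``n -> n+1`` at rate ``k_off * (N_T - n)`` (dissociation of a
  membrane molecule);
* death ``n -> n-1`` at rate
  ``k_on*(V_on/V)*n + k_fb*(V_fb/V)*n*(N_T - n)`` (spontaneous
  activation plus recruitment by the ``N_T - n`` membrane molecules).

One-step processes satisfy detailed balance at stationarity, so the
stationary pmf follows from the product recursion
``P_{n+1}/P_n = birth(n)/death(n+1)``, evaluated here in log-space so
that molecule numbers up to ~1e5 do not overflow.

Far below the critical number ``N_star`` the mass concentrates at
``n = N_T`` (everything cytosolic, the buffered off state); far above
it the pmf is essentially Poisson with expectation ``N_star``; near the
transition the pmf can be bimodal even though the deterministic
description is monotone — the stochastic fingerprint of the switch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp
from scipy.stats import poisson

from .model_core import ModelParams

__all__ = [
    "StationaryPmf",
    "transition_rates",
    "stationary_distribution",
    "classify_modality",
    "compare_to_poisson",
    "total_variation",
]


@dataclass(frozen=True)
class StationaryPmf:
    """Stationary probability over cytosolic counts 0..N_T."""

    p: np.ndarray
    modality: str          # "unimodal" | "bimodal"
    modes: tuple           # local-maximum indices

    @property
    def mean(self) -> float:
        return float(np.dot(np.arange(len(self.p)), self.p))


def transition_rates(n: int | np.ndarray, params: ModelParams):
    """Birth and death rates of the cytosolic count at state ``n``."""
    n = np.asarray(n)
    birth = params.k_off * (params.N_T - n)
    death = (
        params.k_on * (params.V_on / params.V) * n
        + params.k_fb * (params.V_fb / params.V) * n * (params.N_T - n)
    )
    return birth, death


def _modes_of(p: np.ndarray, min_mass: float) -> tuple:
    """Strict local maxima after merging plateaus; keep modes whose
    basin (between flanking minima) carries at least ``min_mass``."""
    n = len(p)
    if n == 1:
        return (0,)
    # compress runs of equal values
    starts = [0]
    for i in range(1, n):
        if p[i] != p[starts[-1]]:
            starts.append(i)
    vals = p[starts]
    runs = len(starts)
    ends = starts[1:] + [n]
    cand = []
    for j in range(runs):
        left_ok = j == 0 or vals[j] > vals[j - 1]
        right_ok = j == runs - 1 or vals[j] > vals[j + 1]
        if left_ok and right_ok:
            # representative index: middle of the plateau
            cand.append((starts[j] + ends[j] - 1) // 2)
    if len(cand) <= 1:
        return tuple(cand)
    # basin boundaries at the minimum between consecutive modes
    bounds = [0]
    for a, b in zip(cand[:-1], cand[1:]):
        bounds.append(a + int(np.argmin(p[a:b + 1])))
    bounds.append(n)
    kept = [
        m for m, lo, hi in zip(cand, bounds[:-1], bounds[1:])
        if p[lo:hi].sum() >= min_mass
    ]
    return tuple(kept) if kept else (cand[int(np.argmax(p[cand]))],)


def classify_modality(p: np.ndarray, min_mass: float = 1e-4) -> StationaryPmf:
    """Wrap a raw pmf vector with its modality classification."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or len(p) == 0 or np.any(p < 0):
        raise ValueError("pmf must be a nonnegative 1-D vector")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("pmf must sum to 1")
    modes = _modes_of(p, min_mass)
    modality = "bimodal" if len(modes) >= 2 else "unimodal"
    return StationaryPmf(p=p, modality=modality, modes=modes)


def stationary_distribution(params: ModelParams, min_mass: float = 1e-4) -> StationaryPmf:
    """Stationary pmf of the cytosolic count via the detailed-balance
    product recursion, normalized in log-space.

    With ``k_on = 0`` the state ``n = N_T`` is absorbing (an empty
    membrane can never re-activate) and the point mass there is
    returned.
    """
    N = params.N_T
    if N < 1:
        raise ValueError("N_T must be >= 1")
    if params.k_on == 0:
        p = np.zeros(N + 1)
        p[N] = 1.0
        return classify_modality(p, min_mass)
    n = np.arange(N + 1)
    birth, death = transition_rates(n, params)
    # log P_n - log P_0 = sum_{m=1..n} log(birth(m-1)/death(m))
    with np.errstate(divide="ignore"):
        steps = np.log(birth[:-1]) - np.log(death[1:])
    logp = np.concatenate(([0.0], np.cumsum(steps)))
    p = np.exp(logp - logsumexp(logp))
    p /= p.sum()
    return classify_modality(p, min_mass)


def total_variation(p: np.ndarray, q: np.ndarray) -> float:
    """Total variation distance between two pmfs on the same support."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("pmfs must share a support")
    return 0.5 * float(np.abs(p - q).sum())


def compare_to_poisson(pmf: StationaryPmf, mean: float) -> float:
    """TV distance to a Poisson(mean) truncated to the pmf support."""
    if mean <= 0:
        raise ValueError("mean must be > 0")
    n = len(pmf.p)
    q = poisson.pmf(np.arange(n), mean)
    s = q.sum()
    if s <= 0:
        raise ValueError("Poisson mass entirely outside the support")
    return total_variation(pmf.p, q / s)
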