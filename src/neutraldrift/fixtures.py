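"""Tiny deterministic trajectories with known qualitative structure.

Each fixture is at most a couple of hundred molecules and a couple of
simulated minutes, so analysis code can be unit-tested without running
full-scale simulations.  Tags:

``off_state``
    Buffered off regime, empty membrane throughout.
``polarized``
    Constructed states with >50% of membrane molecules inside a
    0.15 L arc and more than 20 on the membrane.
``homogeneous``
    Constructed states with membrane molecules spread uniformly.
``two_clans``
    A short neutral-drift run started from exactly two clans.
"""

from __future__ import annotations

import numpy as np

from .membrane_sim import ParticleState, Schedule, Trajectory, simulate
from .model_core import ModelParams, table3_params

__all__ = ["make_fixture", "FIXTURE_TAGS"]

FIXTURE_TAGS = ("off_state", "polarized", "homogeneous", "two_clans")


def _static_trajectory(positions_fn, N_T, L, n_records=9, t_end=2.0, seed=0):
    rng = np.random.default_rng(seed)
    times = np.linspace(0.0, t_end, n_records)
    positions, clan_ids, n_mem = [], [], []
    for _ in times:
        pos = positions_fn(rng)
        positions.append(pos)
        clan_ids.append(np.ones(len(pos), dtype=np.int64))
        n_mem.append(len(pos))
    n_mem = np.array(n_mem)
    return Trajectory(
        times=times,
        n_cyt=N_T - n_mem,
        n_mem=n_mem,
        n_tot=np.full(n_records, N_T, dtype=np.int64),
        L=L,
        positions=positions,
        clan_ids=clan_ids,
        seed=seed,
    )


def make_fixture(tag: str, seed: int = 0) -> Trajectory:
    """Generate the named fixture trajectory (deterministic per seed)."""
    if tag == "off_state":
        params = table3_params(100).with_(k_on=0.0)
        return simulate(
            params,
            Schedule(t_end=2.0, record_every=0.25),
            membrane_fraction=0.0,
            seed=seed,
        )
    if tag == "two_clans":
        # supercritical small system so both clans persist a while
        params = table3_params(100).with_(k_on=0.0, k_fb=0.45, D_m=0.1)
        return simulate(
            params,
            Schedule(t_end=2.0, record_every=0.25),
            membrane_fraction=0.5,
            n_clans=2,
            seed=seed,
        )
    L = table3_params(1).L
    if tag == "polarized":
        # 30 of 40 membrane molecules inside a 0.15 L arc
        def positions_fn(rng):
            tight = rng.uniform(0.4 * L, 0.55 * L, size=30)
            rest = rng.uniform(0.0, L, size=10)
            return np.concatenate([tight, rest])

        return _static_trajectory(positions_fn, N_T=200, L=L, seed=seed)
    if tag == "homogeneous":
        def positions_fn(rng):
            return rng.uniform(0.0, L, size=150)

        return _static_trajectory(positions_fn, N_T=200, L=L, seed=seed)
    raise ValueError(f"unknown fixture tag {tag!r}; expected one of {FIXTURE_TAGS}")
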