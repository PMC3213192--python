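"""Stochastic particle simulation on a 1-D circular membrane.

Active molecules live at angular positions on a circle of circumference
``L`` and carry clan labels tracing their recruitment genealogy; the
inactive pool is well-mixed and represented only by its count ``N_c``.
Each fixed time step applies, in order:

1. dissociation — every membrane molecule detaches with probability
   ``k_off*dt`` (its clan identity is erased with it);
2. recruitment — every surviving membrane molecule recruits a cytosolic
   molecule with probability ``k_fb*(V_fb/V)*N_c*dt``; the recruit
   appears exactly at the recruiter's position and inherits its clan;
3. spontaneous on-events — ``Poisson(k_on*(V_on/V)*N_c*dt)`` molecules
   attach at uniform positions, each founding a fresh clan;
4. diffusion — every membrane molecule takes a Gaussian step of
   variance ``2*D_m*dt``, wrapped mod ``L``.

The step size is validated so every per-molecule event probability
stays below 0.1; mass conservation ``N_m + N_c = N_T`` is exact.
Perturbation protocols (reseeding cytosolic molecules into a membrane
window, adding/removing cytosolic molecules) reproduce the
restimulation and titration experiments of the switch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import h5py
import numpy as np

from .model_core import InvalidParamsError, ModelParams

__all__ = [
    "ParticleState",
    "Perturbation",
    "Schedule",
    "Trajectory",
    "StepSizeError",
    "default_dt",
    "init_state",
    "step",
    "simulate",
    "kymograph",
]

MAX_EVENT_PROB = 0.1


class StepSizeError(ValueError):
    """dt violates the per-molecule event-probability bound."""


@dataclass
class ParticleState:
    """Positions and clan labels of membrane molecules plus the
    cytosolic count; ``len(positions) + N_c == N_T`` always."""

    t: float
    positions: np.ndarray   # float, in [0, L)
    clan_ids: np.ndarray    # int, parallel to positions
    N_c: int
    N_T: int
    L: float
    next_clan_id: int = 1

    @property
    def N_m(self) -> int:
        return len(self.positions)

    def check(self) -> None:
        if self.N_m + self.N_c != self.N_T:
            raise AssertionError("mass conservation violated")
        if len(self.clan_ids) != self.N_m:
            raise AssertionError("clan labels out of sync")
        if self.N_m and (self.positions.min() < 0 or self.positions.max() >= self.L):
            raise AssertionError("positions outside [0, L)")


@dataclass(frozen=True)
class Perturbation:
    """One scheduled intervention.

    kind ``reseed``: move ``round(fraction * N_c)`` cytosolic molecules
    to uniform positions within one randomly placed window covering
    ``window_fraction`` of the membrane (fresh clan ids).
    kind ``add_cytosol`` / ``remove_cytosol``: change N_c and N_T by
    ``count`` (removal exceeding N_c is an error, raised before any
    mutation).
    """

    kind: str
    fraction: float = 0.0
    window_fraction: float = 0.0
    count: int = 0

    def __post_init__(self):
        if self.kind not in ("reseed", "add_cytosol", "remove_cytosol"):
            raise ValueError(f"unknown perturbation kind {self.kind!r}")
        if self.kind == "reseed" and not (0.0 <= self.fraction <= 1.0 and 0.0 < self.window_fraction <= 1.0):
            raise ValueError("reseed needs fraction in [0,1] and window_fraction in (0,1]")
        if self.kind != "reseed" and self.count < 0:
            raise ValueError("count must be >= 0")


@dataclass(frozen=True)
class Schedule:
    """Simulation horizon, recording cadence and timed perturbations."""

    t_end: float
    record_every: float = 0.5
    events: tuple = ()   # of (time, Perturbation)

    def __post_init__(self):
        if self.t_end <= 0 or self.record_every <= 0:
            raise ValueError("t_end and record_every must be > 0")
        times = [t for t, _ in self.events]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("event times must be strictly increasing")
        if times and (times[0] < 0 or times[-1] > self.t_end):
            raise ValueError("event times must lie within [0, t_end]")


@dataclass
class Trajectory:
    """Recorded time series of a run.

    Count series are always present; per-record positions/clan labels
    are kept only when the run was recorded with
    ``record_positions=True`` (they dominate memory for long runs).
    """

    times: np.ndarray
    n_cyt: np.ndarray
    n_mem: np.ndarray
    n_tot: np.ndarray
    L: float
    positions: list | None = None
    clan_ids: list | None = None
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.times)

    def state_at(self, i: int) -> ParticleState:
        if self.positions is None:
            raise ValueError("trajectory was recorded without positions")
        return ParticleState(
            t=float(self.times[i]),
            positions=self.positions[i],
            clan_ids=self.clan_ids[i],
            N_c=int(self.n_cyt[i]),
            N_T=int(self.n_tot[i]),
            L=self.L,
        )

    def to_hdf5(self, path, config_yaml: str | None = None) -> None:
        with h5py.File(path, "w") as f:
            f.attrs["L"] = self.L
            if self.seed is not None:
                f.attrs["seed"] = self.seed
            if config_yaml is not None:
                f.attrs["config"] = config_yaml
            for name in ("times", "n_cyt", "n_mem", "n_tot"):
                f.create_dataset(name, data=getattr(self, name))
            if self.positions is not None:
                g = f.create_group("records")
                vf = h5py.vlen_dtype(np.float64)
                vi = h5py.vlen_dtype(np.int64)
                dp = g.create_dataset("positions", (len(self.positions),), dtype=vf)
                dc = g.create_dataset("clan_ids", (len(self.clan_ids),), dtype=vi)
                for i, (p, c) in enumerate(zip(self.positions, self.clan_ids)):
                    dp[i] = p
                    dc[i] = c

    @classmethod
    def from_hdf5(cls, path) -> "Trajectory":
        with h5py.File(path, "r") as f:
            kw = {name: f[name][:] for name in ("times", "n_cyt", "n_mem", "n_tot")}
            kw["L"] = float(f.attrs["L"])
            kw["seed"] = int(f.attrs["seed"]) if "seed" in f.attrs else None
            if "records" in f:
                kw["positions"] = [np.asarray(p) for p in f["records/positions"][:]]
                kw["clan_ids"] = [np.asarray(c) for c in f["records/clan_ids"][:]]
        return cls(**kw)


def default_dt(params: ModelParams, safety: float = MAX_EVENT_PROB) -> float:
    """Largest dt keeping every per-molecule event probability < safety,
    using the worst case N_c = N_T for the density-dependent rates."""
    per_mol = max(
        params.k_off,
        params.k_fb * (params.V_fb / params.V) * params.N_T,
        params.k_on * (params.V_on / params.V),
    )
    if per_mol == 0:
        return 0.1
    return safety / per_mol * 0.999


def init_state(
    params: ModelParams,
    membrane_fraction: float,
    n_clans: int = 50,
    rng: np.random.Generator | None = None,
) -> ParticleState:
    """Seed ``round(membrane_fraction * N_T)`` molecules uniformly on
    the circle; clans are the ``n_clans`` equal arcs of the circle."""
    if not (0.0 <= membrane_fraction <= 1.0):
        raise InvalidParamsError("membrane_fraction must be in [0, 1]")
    if n_clans < 1:
        raise InvalidParamsError("n_clans must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    n_m = int(round(membrane_fraction * params.N_T))
    pos = rng.uniform(0.0, params.L, size=n_m)
    # arc index + 1 so clan ids start at 1
    clans = (pos / params.L * n_clans).astype(np.int64) + 1
    return ParticleState(
        t=0.0,
        positions=pos,
        clan_ids=clans,
        N_c=params.N_T - n_m,
        N_T=params.N_T,
        L=params.L,
        next_clan_id=n_clans + 1,
    )


def step(
    state: ParticleState,
    params: ModelParams,
    dt: float,
    rng: np.random.Generator,
) -> ParticleState:
    """Advance one operator-split step (reactions, then diffusion).

    Dissociation is sampled on the pre-step membrane set before
    recruitment; recruitment and on-event propensities use the
    start-of-step cytosolic count.  Mutates and returns ``state``.
    """
    vol = params.V
    p_off = params.k_off * dt
    p_rec = params.k_fb * (params.V_fb / vol) * state.N_c * dt
    p_on = params.k_on * (params.V_on / vol) * dt  # per cytosolic molecule
    if p_off >= MAX_EVENT_PROB or p_rec >= MAX_EVENT_PROB or p_on >= MAX_EVENT_PROB:
        raise StepSizeError(
            f"dt={dt} too large: per-molecule probabilities "
            f"p_off={p_off:.3g}, p_recruit={p_rec:.3g}, p_on={p_on:.3g} "
            f"must stay below {MAX_EVENT_PROB}"
        )
    pos, clans = state.positions, state.clan_ids
    n_m = len(pos)

    # (a) dissociation
    if n_m and p_off > 0:
        keep = rng.random(n_m) >= p_off
        pos, clans = pos[keep], clans[keep]
    n_off = n_m - len(pos)

    # (b) recruitment by survivors (start-of-step N_c propensity)
    n_surv = len(pos)
    if n_surv and p_rec > 0 and state.N_c > 0:
        rec = np.nonzero(rng.random(n_surv) < p_rec)[0]
    else:
        rec = np.empty(0, dtype=np.int64)

    # (c) spontaneous on-events
    n_on = int(rng.poisson(p_on * state.N_c)) if p_on > 0 and state.N_c > 0 else 0

    # cap total draws by the available cytosolic pool (O(dt^2) correction)
    n_avail = state.N_c
    if len(rec) + n_on > n_avail:
        n_on = min(n_on, max(0, n_avail - len(rec)))
        if len(rec) > n_avail:
            rec = rng.permutation(rec)[:n_avail]

    new_pos = [pos]
    new_clans = [clans]
    if len(rec):
        new_pos.append(pos[rec])
        new_clans.append(clans[rec])
    if n_on:
        new_pos.append(rng.uniform(0.0, state.L, size=n_on))
        new_clans.append(np.arange(state.next_clan_id, state.next_clan_id + n_on, dtype=np.int64))
        state.next_clan_id += n_on
    if len(new_pos) > 1:
        pos = np.concatenate(new_pos)
        clans = np.concatenate(new_clans)

    # (d) diffusion
    if params.D_m > 0 and len(pos):
        pos = (pos + rng.normal(0.0, math.sqrt(2.0 * params.D_m * dt), size=len(pos))) % state.L

    state.positions = pos
    state.clan_ids = clans
    state.N_c += n_off - len(rec) - n_on
    state.t += dt
    return state


def _apply_perturbation(state: ParticleState, pert: Perturbation, rng: np.random.Generator) -> None:
    if pert.kind == "add_cytosol":
        state.N_c += pert.count
        state.N_T += pert.count
    elif pert.kind == "remove_cytosol":
        if pert.count > state.N_c:
            raise ValueError(
                f"cannot remove {pert.count} cytosolic molecules: only {state.N_c} present"
            )
        state.N_c -= pert.count
        state.N_T -= pert.count
    else:  # reseed
        n_move = int(round(pert.fraction * state.N_c))
        if n_move == 0:
            return
        start = rng.uniform(0.0, state.L)
        width = pert.window_fraction * state.L
        pos = (start + rng.uniform(0.0, width, size=n_move)) % state.L
        ids = np.arange(state.next_clan_id, state.next_clan_id + n_move, dtype=np.int64)
        state.next_clan_id += n_move
        state.positions = np.concatenate([state.positions, pos])
        state.clan_ids = np.concatenate([state.clan_ids, ids])
        state.N_c -= n_move


def simulate(
    params: ModelParams,
    schedule: Schedule,
    membrane_fraction: float = 0.1,
    n_clans: int = 50,
    seed: int | np.random.Generator | None = 0,
    dt: float | None = None,
    record_positions: bool = True,
    initial_state: ParticleState | None = None,
) -> Trajectory:
    """Run the circuit under a schedule; deterministic given the seed.

    The step size divides ``record_every`` exactly so records land on
    the requested grid; perturbations are applied at the first record
    boundary at or after their scheduled time.
    """
    if params.geometry != "circle1d":
        raise InvalidParamsError("membrane_sim handles the circle1d geometry")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if dt is None:
        # size the step for the largest molecule count the schedule reaches
        n_max = running = params.N_T
        for _, pert in schedule.events:
            if pert.kind == "add_cytosol":
                running += pert.count
            elif pert.kind == "remove_cytosol":
                running -= pert.count
            n_max = max(n_max, running)
        dt = default_dt(params.with_(N_T=n_max))
    n_sub = max(1, math.ceil(schedule.record_every / dt))
    dt = schedule.record_every / n_sub
    if initial_state is not None:
        state = initial_state
    else:
        state = init_state(params, membrane_fraction, n_clans, rng)

    n_rec = int(round(schedule.t_end / schedule.record_every)) + 1
    times = np.empty(n_rec)
    n_cyt = np.empty(n_rec, dtype=np.int64)
    n_mem = np.empty(n_rec, dtype=np.int64)
    n_tot = np.empty(n_rec, dtype=np.int64)
    positions = [] if record_positions else None
    clan_ids = [] if record_positions else None
    events = list(schedule.events)

    def record(i: int) -> None:
        times[i] = state.t
        n_cyt[i] = state.N_c
        n_mem[i] = state.N_m
        n_tot[i] = state.N_T
        if record_positions:
            positions.append(state.positions.copy())
            clan_ids.append(state.clan_ids.copy())
        state.check()

    record(0)
    for i in range(1, n_rec):
        t_next = i * schedule.record_every
        while events and events[0][0] <= state.t + 1e-12:
            _, pert = events.pop(0)
            _apply_perturbation(state, pert, rng)
        for _ in range(n_sub):
            step(state, params, dt, rng)
        state.t = t_next  # suppress fp drift on the record grid
        record(i)
    return Trajectory(
        times=times, n_cyt=n_cyt, n_mem=n_mem, n_tot=n_tot, L=params.L,
        positions=positions, clan_ids=clan_ids,
        seed=seed if isinstance(seed, int) else None,
    )


def kymograph(traj: Trajectory, n_bins: int) -> np.ndarray:
    """Space-time matrix of membrane molecule counts.

    Rows are recorded times, columns equal half-open arcs starting at
    angle 0; row sums equal the membrane counts.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if traj.positions is None:
        raise ValueError("trajectory was recorded without positions")
    out = np.zeros((len(traj), n_bins), dtype=np.int64)
    edges = np.linspace(0.0, traj.L, n_bins + 1)
    for i, pos in enumerate(traj.positions):
        if len(pos):
            out[i] = np.histogram(pos, bins=edges)[0]
    return out
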