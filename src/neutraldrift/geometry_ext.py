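"""Brownian-dynamics variant with an explicitly diffusing inactive pool.

The well-mixed-cytosol assumption of the 1-D circle model is dropped:
inactive molecules diffuse at a finite rate ``D_c`` (still faster than
the active rate ``D_m``) and recruitment becomes a proximity reaction —
an (active, inactive) pair closer than ``reaction_radius`` converts the
inactive molecule with probability ``p_react`` per step, placing it at
the recruiter's position with the recruiter's clan label.  Three
geometries are supported:

* ``sphere_surface_interior`` — active molecules on the surface of a
  sphere of radius ``L``, inactive molecules in its interior (polarity);
* ``disk2d`` — both species on a periodic square of side ``L``
  (membrane microdomains);
* ``box3d`` — both species in a periodic cube of side ``L`` (nuclear /
  cytosolic clustering).

In the well-mixed limit (large ``D_c``, reaction-limited ``p_react``)
the scheme reduces to mass action with an effective bimolecular
coefficient ``k_fb*V_fb = p_react * v_r / dt`` where ``v_r`` is the
reaction-neighborhood measure (``pi*r^2`` in 2-D, ``4/3*pi*r^3`` in
3-D); :func:`effective_rate_map` exposes that correspondence so
geometry runs can be placed on the analytic phase plane.  This is an
approximation in the spirit of Smoluchowski reaction dynamics, not a
reimplementation of any particular simulator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .model_core import InvalidParamsError, ModelParams

__all__ = [
    "GeometryState",
    "GeometryTrajectory",
    "effective_rate_map",
    "calibrate_p_react",
    "init_geometry_state",
    "simulate_geometry",
]

MAX_EVENT_PROB = 0.1


@dataclass
class GeometryState:
    t: float
    active_positions: np.ndarray    # (n_a, dim)
    inactive_positions: np.ndarray  # (n_i, dim)
    clan_ids: np.ndarray
    N_T: int
    geometry: str
    L: float
    next_clan_id: int = 1

    @property
    def n_active(self) -> int:
        return len(self.active_positions)

    @property
    def n_inactive(self) -> int:
        return len(self.inactive_positions)

    def check(self) -> None:
        if self.n_active + self.n_inactive != self.N_T:
            raise AssertionError("mass conservation violated")
        if self.geometry == "sphere_surface_interior" and self.n_active:
            r = np.linalg.norm(self.active_positions, axis=1)
            if np.any(np.abs(r - self.L) > 1e-9 * self.L):
                raise AssertionError("active molecules left the sphere surface")


@dataclass
class GeometryTrajectory:
    times: np.ndarray
    n_active: np.ndarray
    n_inactive: np.ndarray
    geometry: str
    L: float
    states: list | None = None  # recorded GeometryState snapshots


def _neighborhood_measure(reaction_radius: float, geometry: str) -> float:
    if geometry in ("disk2d",):
        return math.pi * reaction_radius**2
    return 4.0 / 3.0 * math.pi * reaction_radius**3


def effective_rate_map(
    params: ModelParams, reaction_radius: float, p_react: float, dt: float
) -> float:
    """Well-mixed-limit bimolecular coefficient ``k_fb * V_fb`` implied
    by the (radius, p_react, dt) reaction scheme.

    A uniformly distributed inactive molecule lies within the reaction
    neighborhood of a given active molecule with probability
    ``v_r / V`` and converts with probability ``p_react`` per step, so
    the per-pair rate is ``p_react * v_r / (V * dt)`` and the
    volume-independent coefficient is ``p_react * v_r / dt``.
    """
    if reaction_radius <= 0 or dt <= 0:
        raise ValueError("reaction_radius and dt must be > 0")
    if not (0.0 <= p_react <= 1.0):
        raise ValueError("p_react must lie in [0, 1]")
    v_r = _neighborhood_measure(reaction_radius, params.geometry)
    return p_react * v_r / dt


def calibrate_p_react(
    params: ModelParams, reaction_radius: float, dt: float
) -> float:
    """Per-step reaction probability reproducing ``params.k_fb * V_fb``
    in the well-mixed limit (inverse of :func:`effective_rate_map`)."""
    v_r = _neighborhood_measure(reaction_radius, params.geometry)
    p = params.k_fb * params.V_fb * dt / v_r
    if p > 1.0:
        raise ValueError(
            f"required p_react = {p:.3g} > 1: increase reaction_radius or decrease dt"
        )
    return p


def _random_in_domain(n, geometry, L, rng):
    if geometry == "disk2d":
        return rng.uniform(0.0, L, size=(n, 2))
    if geometry == "box3d":
        return rng.uniform(0.0, L, size=(n, 3))
    # sphere interior: rejection-free radial sampling
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    r = L * rng.random(n) ** (1.0 / 3.0)
    return v * r[:, None]


def _random_on_surface(n, L, rng):
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return v * L


def init_geometry_state(
    params: ModelParams,
    active_fraction: float = 0.1,
    rng: np.random.Generator | None = None,
) -> GeometryState:
    """Seed ``round(active_fraction * N_T)`` active molecules uniformly
    on the active manifold (each its own clan) and the rest uniformly
    in the inactive compartment."""
    rng = np.random.default_rng() if rng is None else rng
    if not (0.0 <= active_fraction <= 1.0):
        raise InvalidParamsError("active_fraction must be in [0, 1]")
    n_a = int(round(active_fraction * params.N_T))
    geom, L = params.geometry, params.L
    if geom == "sphere_surface_interior":
        act = _random_on_surface(n_a, L, rng)
    else:
        act = _random_in_domain(n_a, geom, L, rng)
    inact = _random_in_domain(params.N_T - n_a, geom, L, rng)
    return GeometryState(
        t=0.0,
        active_positions=act,
        inactive_positions=inact,
        clan_ids=np.arange(1, n_a + 1, dtype=np.int64),
        N_T=params.N_T,
        geometry=geom,
        L=L,
        next_clan_id=n_a + 1,
    )


def _diffuse_active(pos, D, dt, geometry, L, rng):
    if len(pos) == 0 or D == 0:
        return pos
    sigma = math.sqrt(2.0 * D * dt)
    if geometry == "sphere_surface_interior":
        # tangent-plane Gaussian step + radial re-projection
        stepv = rng.normal(0.0, sigma, size=pos.shape)
        radial = pos / L
        stepv -= (stepv * radial).sum(axis=1, keepdims=True) * radial
        pos = pos + stepv
        pos *= L / np.linalg.norm(pos, axis=1, keepdims=True)
        return pos
    return (pos + rng.normal(0.0, sigma, size=pos.shape)) % L


def _diffuse_inactive(pos, D, dt, geometry, L, rng):
    if len(pos) == 0 or D == 0:
        return pos
    if not math.isfinite(D):
        # infinite diffusivity: resample uniformly (well-mixed pool)
        return _random_in_domain(len(pos), geometry, L, rng)
    pos = pos + rng.normal(0.0, math.sqrt(2.0 * D * dt), size=pos.shape)
    if geometry == "sphere_surface_interior":
        r = np.linalg.norm(pos, axis=1)
        out = r > L
        if out.any():  # radial reflection at the membrane
            r_ref = np.minimum(np.abs(2.0 * L - r[out]), L * (1 - 1e-12))
            pos[out] *= (r_ref / r[out])[:, None]
        return pos
    return pos % L


def simulate_geometry(
    params: ModelParams,
    reaction_radius: float,
    t_end: float,
    dt: float,
    p_react: float | None = None,
    record_every: float = 0.5,
    active_fraction: float = 0.1,
    seed: int | np.random.Generator | None = 0,
    record_states: bool = False,
) -> GeometryTrajectory:
    """Fixed-step Brownian dynamics with proximity recruitment.

    Per step: both species diffuse; every (active, inactive) pair
    within ``reaction_radius`` reacts with probability ``p_react``
    (at most one conversion per inactive molecule, pair order
    randomized); each inactive molecule activates spontaneously with
    probability ``k_on*(V_on/V)*dt`` (sphere case: projected to the
    surface); each active molecule inactivates with probability
    ``k_off*dt`` (sphere case: released just inside the surface).

    If ``p_react`` is omitted it is calibrated so the well-mixed limit
    reproduces ``params.k_fb * V_fb``.
    """
    if params.geometry == "circle1d":
        raise InvalidParamsError("use membrane_sim for the circle1d geometry")
    if reaction_radius <= 0:
        raise ValueError("reaction_radius must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if p_react is None:
        p_react = calibrate_p_react(params, reaction_radius, dt)
    p_off = params.k_off * dt
    p_on = params.k_on * (params.V_on / params.V) * dt
    if p_off >= MAX_EVENT_PROB or p_on >= MAX_EVENT_PROB or p_react >= MAX_EVENT_PROB:
        raise ValueError(
            f"step probabilities p_off={p_off:.3g}, p_on={p_on:.3g}, "
            f"p_react={p_react:.3g} must stay below {MAX_EVENT_PROB}"
        )

    state = init_geometry_state(params, active_fraction, rng)
    periodic = params.geometry in ("disk2d", "box3d")
    boxsize = params.L if periodic else None

    n_sub = max(1, math.ceil(record_every / dt))
    dt = record_every / n_sub
    n_rec = int(round(t_end / record_every)) + 1
    times = np.empty(n_rec)
    n_act = np.empty(n_rec, dtype=np.int64)
    n_inact = np.empty(n_rec, dtype=np.int64)
    states = [] if record_states else None

    def record(i):
        times[i] = state.t
        n_act[i] = state.n_active
        n_inact[i] = state.n_inactive
        if record_states:
            states.append(
                GeometryState(
                    t=state.t,
                    active_positions=state.active_positions.copy(),
                    inactive_positions=state.inactive_positions.copy(),
                    clan_ids=state.clan_ids.copy(),
                    N_T=state.N_T,
                    geometry=state.geometry,
                    L=state.L,
                )
            )
        state.check()

    record(0)
    for i in range(1, n_rec):
        for _ in range(n_sub):
            _step_geometry(state, params, reaction_radius, p_react, p_off, p_on,
                           dt, periodic, boxsize, rng)
        state.t = i * record_every
        record(i)
    return GeometryTrajectory(
        times=times, n_active=n_act, n_inactive=n_inact,
        geometry=params.geometry, L=params.L, states=states,
    )


def _step_geometry(state, params, radius, p_react, p_off, p_on, dt,
                   periodic, boxsize, rng):
    act, inact, clans = state.active_positions, state.inactive_positions, state.clan_ids

    # inactivation (active -> inactive, in place)
    if len(act) and p_off > 0:
        off = rng.random(len(act)) < p_off
        if off.any():
            released = act[off]
            if state.geometry == "sphere_surface_interior":
                released = released * 0.999  # just inside the surface
            inact = np.vstack([inact, released]) if len(inact) else released
            act, clans = act[~off], clans[~off]

    # recruitment: pairs within radius, randomized order, one
    # conversion per inactive molecule
    if len(act) and len(inact) and p_react > 0:
        tree = cKDTree(inact, boxsize=boxsize)
        pairs = []
        hits = tree.query_ball_point(act, radius)
        for a_idx, lst in enumerate(hits):
            pairs.extend((a_idx, i_idx) for i_idx in lst)
        if pairs:
            order = rng.permutation(len(pairs))
            fire = rng.random(len(pairs)) < p_react
            converted: dict[int, int] = {}
            for j in order:
                if not fire[j]:
                    continue
                a_idx, i_idx = pairs[j]
                if i_idx not in converted:
                    converted[i_idx] = a_idx
            if converted:
                i_list = np.fromiter(converted.keys(), dtype=np.int64)
                a_list = np.fromiter(converted.values(), dtype=np.int64)
                act = np.vstack([act, act[a_list]])
                clans = np.concatenate([clans, clans[a_list]])
                keep = np.ones(len(inact), dtype=bool)
                keep[i_list] = False
                inact = inact[keep]

    # spontaneous activation
    if len(inact) and p_on > 0:
        on = rng.random(len(inact)) < p_on
        if on.any():
            newly = inact[on]
            if state.geometry == "sphere_surface_interior":
                norms = np.linalg.norm(newly, axis=1, keepdims=True)
                norms[norms == 0] = 1.0
                newly = newly / norms * state.L
            act = np.vstack([act, newly]) if len(act) else newly
            n_new = int(on.sum())
            clans = np.concatenate([
                clans,
                np.arange(state.next_clan_id, state.next_clan_id + n_new, dtype=np.int64),
            ])
            state.next_clan_id += n_new
            inact = inact[~on]

    # diffusion
    act = _diffuse_active(act, params.D_m, dt, state.geometry, state.L, rng)
    inact = _diffuse_inactive(inact, params.D_c, dt, state.geometry, state.L, rng)

    state.active_positions = act
    state.inactive_positions = inact
    state.clan_ids = clans
    state.t += dt
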