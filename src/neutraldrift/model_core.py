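"""Parameters, derived constants, and closed-form regime predicates.

The model is a two-state positive-feedback circuit: a single molecular
species cycles between an inactive (cytosolic, well-mixed) form and an
active (membrane-bound, slowly diffusing) form via three mass-action
mechanisms —

* spontaneous inactivation of a membrane molecule at rate ``k_off``;
* spontaneous activation of a cytosolic molecule within a shell of
  volume ``V_on`` near the membrane at rate ``k_on``;
* recruitment: an active molecule converts a cytosolic molecule found in
  its feedback volume ``V_fb`` at rate ``k_fb``, placing the recruit at
  its own membrane position (the positive feedback).

All behavior is organized by a handful of derived constants, most
importantly the critical density ``rho_star = k_off / (k_fb * V_fb)``
and the ratio ``R0 = rho_T / rho_star``, the analogue of the basic
reproductive ratio of an SIS epidemic: membrane accumulation is
repressed for ``R0 < 1`` and permitted for ``R0 > 1``.

Units throughout: minutes and micrometers (volumes/areas in the matching
power of µm). The default parameter set uses the unit-domain convention
``V = V_on = V_fb = 1`` so the composite rates act directly as
per-molecule propensity coefficients and ``N_star = k_off / k_fb``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

__all__ = [
    "ModelParams",
    "DerivedConstants",
    "RegimeBounds",
    "InvalidParamsError",
    "NoFeedbackError",
    "table3_params",
    "derive_constants",
    "regime_bounds",
    "GEOMETRIES",
]

GEOMETRIES = ("circle1d", "sphere_surface_interior", "disk2d", "box3d")

#: default membrane circumference for the 1-D circle: a cell of radius
#: 5 µm; see docs/methods.md for the choice of scale.
DEFAULT_CIRCUMFERENCE = 2.0 * math.pi * 5.0


class InvalidParamsError(ValueError):
    """A parameter set violates the model invariants."""


class NoFeedbackError(InvalidParamsError):
    """k_fb or V_fb is zero: rho_star is undefined (no-feedback model)."""


@dataclass(frozen=True)
class ModelParams:
    """Rate constants, reaction volumes and compartment description.

    Attributes
    ----------
    k_off : float
        Spontaneous membrane->cytosol inactivation rate, 1/min.
    k_on : float
        Spontaneous activation rate constant, 1/min.
    k_fb : float
        Recruitment (feedback) rate constant, 1/min.
    V_on, V_fb, V : float
        Activation shell, feedback neighborhood, and total compartment
        size (volume, or area in 2-D), same length-dimension as V.
    N_T : int
        Total (conserved) molecule number.
    D_m : float
        Lateral diffusivity of active molecules, µm²/min.
    D_c : float
        Diffusivity of the inactive pool; ``math.inf`` means the
        well-mixed assumption (mandatory for the 1-D circle model).
    geometry : str
        One of ``circle1d``, ``sphere_surface_interior``, ``disk2d``,
        ``box3d``.
    L : float
        Length descriptor of the active compartment: circumference of
        the 1-D circle, sphere radius, or box/plane side length, µm.
    """

    N_T: int
    k_off: float = 9.0
    k_on: float = 0.0005
    k_fb: float = 0.01
    V_on: float = 1.0
    V_fb: float = 1.0
    V: float = 1.0
    D_m: float = 1.2
    D_c: float = math.inf
    geometry: str = "circle1d"
    L: float = DEFAULT_CIRCUMFERENCE

    def __post_init__(self) -> None:
        for name in ("k_off", "k_on", "k_fb"):
            if getattr(self, name) < 0:
                raise InvalidParamsError(f"{name} must be >= 0, got {getattr(self, name)}")
        for name in ("V", "V_on", "V_fb", "L"):
            if getattr(self, name) <= 0:
                raise InvalidParamsError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.N_T < 0 or self.N_T != int(self.N_T):
            raise InvalidParamsError(f"N_T must be a nonnegative integer, got {self.N_T}")
        if self.D_m < 0 or self.D_c < 0:
            raise InvalidParamsError("diffusivities must be >= 0")
        if self.geometry not in GEOMETRIES:
            raise InvalidParamsError(f"unknown geometry {self.geometry!r}")
        if math.isfinite(self.D_c) and self.geometry == "circle1d":
            raise InvalidParamsError(
                "the 1-D circle model assumes a well-mixed cytosol (D_c = inf); "
                "use a finite-D_c geometry for an explicitly diffusing pool"
            )
        if self.V_on > self.V or self.V_fb > self.V:
            raise InvalidParamsError("V_on and V_fb cannot exceed the compartment size V")

    def with_(self, **kwargs) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


def table3_params(N_T: int, **overrides) -> ModelParams:
    """The default (literature-derived) rate set on the unit domain.

    k_off = 9/min, k_on = 5e-4/min, k_fb = 0.01/min, D_m = 1.2 µm²/min,
    V = V_on = V_fb = 1, so N_star = k_off/k_fb = 900.
    """
    return ModelParams(N_T=N_T, **overrides)


@dataclass(frozen=True)
class DerivedConstants:
    """Constants derived from a :class:`ModelParams`.

    ``rho_T`` is the total molecule density (the ceiling for the
    cytosolic density); ``rho_star`` the feedback-independent critical
    density; ``alpha_on_off`` the spontaneous on-to-off ratio (the small
    imperfection parameter of the bifurcation); ``beta_on_fb`` the
    on-to-feedback ratio governing the stochastic clustering analysis;
    ``R0 = rho_T/rho_star``; ``N_star = rho_star*V`` the critical
    molecule number.
    """

    rho_T: float
    rho_star: float
    alpha_on_off: float
    beta_on_fb: float
    R0: float
    N_star: float


def derive_constants(params: ModelParams) -> DerivedConstants:
    """Compute all derived constants. Pure; rejects the no-feedback case."""
    if params.k_fb == 0 or params.V_fb == 0:
        raise NoFeedbackError(
            "k_fb and V_fb must be positive: without feedback rho_star is undefined"
        )
    rho_T = params.N_T / params.V
    rho_star = params.k_off / (params.k_fb * params.V_fb)
    alpha = (params.k_on * params.V_on) / (params.k_off * params.V) if params.k_off > 0 else math.inf
    beta = (params.k_on * params.V_on) / (params.k_fb * params.V_fb)
    if params.k_on == 0:
        alpha = 0.0
    R0 = rho_T / rho_star if rho_star > 0 else math.inf
    N_star = rho_star * params.V
    return DerivedConstants(
        rho_T=rho_T,
        rho_star=rho_star,
        alpha_on_off=alpha,
        beta_on_fb=beta,
        R0=R0,
        N_star=N_star,
    )


LN2 = math.log(2.0)


@dataclass(frozen=True)
class RegimeBounds:
    """Outcome of the two closed-form polarization predicates.

    ``single_clan_bound_ok`` — spontaneous on-events are rare enough
    that, by the single-clan consolidation time, all but a fraction
    ``delta`` of membrane molecules belong to one clan.

    ``locality_bound_ok`` — membrane diffusion is slow enough that the
    winning clan stays within a neighborhood of its founding site.
    """

    single_clan_bound_ok: bool
    locality_bound_ok: bool
    delta: float
    K: int
    C_locality: float


#: order-one geometry/initial-region constant of the locality bound
DEFAULT_C_LOCALITY = 0.25


def regime_bounds(
    params: ModelParams,
    K: int,
    delta: float = 0.1,
    C_locality: float = DEFAULT_C_LOCALITY,
) -> RegimeBounds:
    """Evaluate the on-rarity and diffusion-locality inequalities.

    The on-rarity bound requires the expected standing population of
    spontaneous-origin membrane molecules accumulated over the
    single-clan consolidation time to be at most a fraction ``delta`` of
    the membrane population:

        beta_on_fb * (1 - 1/K) / ln 2  <=  delta

    (``beta_on_fb = k_on*V_on/(k_fb*V_fb)``; the K-dependent factor is
    the consolidation time in units of the neutral-drift timescale).

    The locality bound requires the diffusive spread accumulated during
    consolidation to stay below the compartment scale; it caps the
    molecule number:

        N_T  <=  N_star + C * L^2 * k_off / D_m

    with ``C`` an order-one constant set by the initial clan-region
    size. ``D_m = 0`` satisfies the bound for any finite ``N_T``.
    """
    if K < 1 or K != int(K):
        raise InvalidParamsError(f"K must be a positive integer, got {K}")
    if not (0.0 < delta < 1.0):
        raise InvalidParamsError(f"delta must lie in (0, 1), got {delta}")
    consts = derive_constants(params)
    single_ok = consts.beta_on_fb * (1.0 - 1.0 / K) / LN2 <= delta
    if params.D_m == 0:
        local_ok = True
    else:
        n_max = consts.N_star + C_locality * params.L**2 * params.k_off / params.D_m
        local_ok = params.N_T <= n_max
    return RegimeBounds(
        single_clan_bound_ok=bool(single_ok),
        locality_bound_ok=bool(local_ok),
        delta=delta,
        K=int(K),
        C_locality=C_locality,
    )
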