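"""Run configuration: YAML round-trip, validation, presets, seeding.

A :class:`RunConfig` bundles the model parameters, the simulation
schedule and the RNG seed, and serializes losslessly to a flat YAML
document.  Unknown keys are rejected loudly so a typo in a config file
cannot silently fall back to a default.  One global seed expands into
independent per-replicate streams via ``numpy.random.SeedSequence``
spawning.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from .membrane_sim import Perturbation, Schedule
from .model_core import ModelParams

__all__ = ["RunConfig", "load_config", "save_config", "spawn_rngs", "PRESETS"]

#: named parameter presets (rates in 1/min, lengths in µm)
PRESETS = {
    "table3": dict(
        k_off=9.0, k_on=0.0005, k_fb=0.01,
        V=1.0, V_on=1.0, V_fb=1.0, D_m=1.2,
    ),
}


@dataclass(frozen=True)
class RunConfig:
    params: ModelParams
    schedule: Schedule
    seed: int = 0
    membrane_fraction: float = 0.1
    n_clans: int = 50
    record_positions: bool = True

    def to_dict(self) -> dict:
        d = dict(
            params={k: (None if isinstance(v, float) and math.isinf(v) else v)
                    for k, v in asdict(self.params).items()},
            schedule=dict(
                t_end=self.schedule.t_end,
                record_every=self.schedule.record_every,
                events=[
                    dict(time=t, **{k: v for k, v in asdict(p).items()})
                    for t, p in self.schedule.events
                ],
            ),
            seed=self.seed,
            membrane_fraction=self.membrane_fraction,
            n_clans=self.n_clans,
            record_positions=self.record_positions,
        )
        return d

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)


_TOP_KEYS = {"params", "schedule", "seed", "membrane_fraction", "n_clans",
             "record_positions", "preset"}
_PARAM_KEYS = {"N_T", "k_off", "k_on", "k_fb", "V_on", "V_fb", "V",
               "D_m", "D_c", "geometry", "L"}
_SCHED_KEYS = {"t_end", "record_every", "events"}
_EVENT_KEYS = {"time", "kind", "fraction", "window_fraction", "count"}


def _reject_unknown(d: dict, allowed: set, where: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ValueError(f"unknown key(s) {sorted(unknown)} in {where}")


def config_from_dict(doc: dict) -> RunConfig:
    if not isinstance(doc, dict):
        raise ValueError("config document must be a mapping")
    _reject_unknown(doc, _TOP_KEYS, "config")
    pdict = dict(PRESETS.get(doc.get("preset", ""), {}))
    user_params = doc.get("params", {}) or {}
    _reject_unknown(user_params, _PARAM_KEYS, "config.params")
    pdict.update(user_params)
    if "N_T" not in pdict:
        raise ValueError("config.params.N_T is required")
    if pdict.get("D_c") is None:
        pdict["D_c"] = math.inf
    try:
        params = ModelParams(**pdict)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid config.params: {exc}") from exc
    sdict = doc.get("schedule", {}) or {}
    _reject_unknown(sdict, _SCHED_KEYS, "config.schedule")
    events = []
    for ev in sdict.get("events", []) or []:
        _reject_unknown(ev, _EVENT_KEYS, "config.schedule.events[]")
        ev = dict(ev)
        t = ev.pop("time")
        events.append((float(t), Perturbation(**ev)))
    schedule = Schedule(
        t_end=float(sdict.get("t_end", 60.0)),
        record_every=float(sdict.get("record_every", 0.5)),
        events=tuple(events),
    )
    return RunConfig(
        params=params,
        schedule=schedule,
        seed=int(doc.get("seed", 0)),
        membrane_fraction=float(doc.get("membrane_fraction", 0.1)),
        n_clans=int(doc.get("n_clans", 50)),
        record_positions=bool(doc.get("record_positions", True)),
    )


def load_config(path) -> RunConfig:
    """Parse and validate a YAML run configuration."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return config_from_dict(doc)


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        fh.write(cfg.to_yaml())


def spawn_rngs(seed: int, n: int) -> list:
    """n independent generators derived from one global seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]
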