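"""Scenario configuration: human-editable YAML to a ready transport model.

A scenario file collects the breathing pattern, wall-layer spec, optional
constriction and mucus, transport parameters and grid resolution::

    breathing: {q_in: 500.0, q_ex: -50.0, t_in: 2.0, t_bh: 0.0, t_ex: 20.0}
    walls: {epithelium_cm: 0.0015, muscle_cm: 0.0030}
    constriction: {beta: 0.9, start_generation: 2, last_generation: 15}
    mucus: {thickness_cm: 0.0005, first_generation: 0, last_generation: 18}
    grid: {points_per_generation: 20}
    cycles: 1

Every block is optional; omitted blocks fall back to the healthy defaults.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import yaml

from .cycle import BreathingPattern
from .lumen import GridSpec, TransportModel
from .morphometry import (
    LAST_WALLED_GENERATION,
    ConstrictionProfile,
    WallLayerSpec,
    apply_alterations,
    load_morphometry,
)
from .wall import AlveolarParams, WallTransportParams

__all__ = ["Scenario", "load_scenario"]


class ConfigError(ValueError):
    """Raised on malformed scenario files."""


@dataclass(frozen=True)
class Scenario:
    model: TransportModel
    cycles: int = 1


def _section(data: dict, name: str) -> dict:
    block = data.get(name) or {}
    if not isinstance(block, dict):
        raise ConfigError(f"section '{name}' must be a mapping")
    return block


def scenario_from_dict(data: dict) -> Scenario:
    """Build a :class:`Scenario` from a parsed configuration mapping."""
    known = {"breathing", "walls", "constriction", "mucus", "grid",
             "transport", "alveolar", "cycles", "morphometry"}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown sections: {sorted(unknown)}")

    table = load_morphometry(data.get("morphometry"))

    b = _section(data, "breathing")
    try:
        pattern = BreathingPattern(
            q_in=float(b.get("q_in", 500.0)),
            q_ex=float(b.get("q_ex", -50.0)),
            t_in=float(b.get("t_in", 2.0)),
            t_bh=float(b.get("t_bh", 0.0)),
            t_ex=float(b.get("t_ex", 20.0)),
        )
    except ValueError as exc:
        raise ConfigError(f"breathing: {exc}") from exc

    w = _section(data, "walls")
    mu = _section(data, "mucus")
    wall_kwargs = {
        "epithelium_cm": float(w.get("epithelium_cm", 0.0015)),
        "muscle_cm": float(w.get("muscle_cm", 0.0030)),
    }
    if mu:
        walls = WallLayerSpec.uniform_mucus(
            float(mu.get("thickness_cm", 0.0)),
            first=int(mu.get("first_generation", 0)),
            last=int(mu.get("last_generation", LAST_WALLED_GENERATION)),
            **wall_kwargs,
        )
    else:
        walls = WallLayerSpec(**wall_kwargs)

    c = _section(data, "constriction")
    if c:
        constriction = ConstrictionProfile.homogeneous_beta(
            float(c["beta"]),
            int(c.get("start_generation", 2)),
            int(c.get("last_generation", LAST_WALLED_GENERATION)),
        )
    else:
        constriction = None

    rest = apply_alterations(table, walls, constriction)
    tp = _section(data, "transport")
    alv = _section(data, "alveolar")
    grid = _section(data, "grid")
    model = TransportModel(
        rest=rest,
        pattern=pattern,
        wall_params=WallTransportParams(**tp) if tp else WallTransportParams(),
        alveolar=AlveolarParams(**alv) if alv else AlveolarParams(),
        grid=GridSpec(int(grid.get("points_per_generation", 20))),
    )
    cycles = int(data.get("cycles", 1))
    if cycles < 1:
        raise ConfigError("cycles must be >= 1")
    return Scenario(model=model, cycles=cycles)


def load_scenario(path: str | Path | None = None) -> Scenario:
    """Load a scenario YAML file (healthy classical defaults when omitted)."""
    if path is None:
        return scenario_from_dict({})
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError("scenario file must contain a mapping")
    return scenario_from_dict(data)
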