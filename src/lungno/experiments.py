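"""Scripted in-silico FE_NO experiments and constriction/mucus comparisons.

Every experiment is a deterministic wrapper around :func:`simulate_cycle`:
the classical FE_NO maneuver, sweeps over expiratory flow and breath-hold
duration, and the unhealthy-vs-healthy comparisons quantified by

* ``d_feno50``  — relative change of the end-expiration FE_NO,
* ``d_j``       — relative change of the zeta-averaged epithelium-to-lumen
  flux density in the last constricted generation at end of expiration,
* ``d_flux``    — relative change of the total epithelium-to-lumen NO flow
  in that generation at end of expiration,

each computed as (unhealthy - healthy) / healthy with both lungs breathing
the same pattern and sharing all transport parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .cycle import BreathingPattern, Phase, wall_radii_at_scale
from .lumen import PPB, SimulationResult, TransportModel, simulate_cycle
from .morphometry import (
    ConstrictionProfile,
    MorphometryTable,
    WallLayerSpec,
    apply_alterations,
    load_morphometry,
)
from .wall import WallTransportParams, airway_flux_law, hatta_numbers, wall_profile

#: constriction is assumed absent from the trachea and main bronchi by default
DEFAULT_START_GENERATION = 2

__all__ = ["ComparisonMetrics", "classical_cycle_experiment", "flow_sweep",
           "breathhold_sweep", "bc_experiment", "wall_profile_report",
           "healthy_model", "DEFAULT_START_GENERATION"]


def healthy_model(
    table: MorphometryTable | None = None,
    pattern: BreathingPattern | None = None,
    **model_kwargs,
) -> TransportModel:
    """Transport model of healthy lungs with the standard parameter set."""
    table = table if table is not None else load_morphometry()
    rest = apply_alterations(table)
    return TransportModel(
        rest=rest,
        pattern=pattern if pattern is not None else BreathingPattern.classical(),
        **model_kwargs,
    )


def classical_cycle_experiment(
    table: MorphometryTable | None = None,
    pattern: BreathingPattern | None = None,
    n_cycles: int = 1,
    **model_kwargs,
) -> SimulationResult:
    """Healthy-lung FE_NO maneuver: 500 ml/s x 2 s in, 50 ml/s x 20 s out."""
    model = healthy_model(table, pattern, **model_kwargs)
    return simulate_cycle(model, n_cycles=n_cycles)


def flow_sweep(
    q_ex_list: list[float],
    table: MorphometryTable | None = None,
    **model_kwargs,
) -> pd.DataFrame:
    """End-expiration FE_NO versus expiratory flow magnitude.

    For each flow the expiration duration is stretched so the expired volume
    equals the inspired volume (``t_ex = q_in t_in / |q_ex|``).  Returns a
    frame sorted by ``abs_q_ex`` regardless of input order.
    """
    table = table if table is not None else load_morphometry()
    rows = []
    for q in sorted(abs(float(v)) for v in q_ex_list):
        pattern = BreathingPattern.with_expiratory_flow(q)
        res = classical_cycle_experiment(table, pattern, **model_kwargs)
        rows.append({"abs_q_ex_ml_per_s": q, "t_ex_s": pattern.t_ex,
                     "feno_end_ppb": res.feno_end_ppb})
    return pd.DataFrame(rows)


def breathhold_sweep(
    t_bh_list: list[float],
    table: MorphometryTable | None = None,
    **model_kwargs,
) -> dict[float, SimulationResult]:
    """FE_NO expiration curves for different breath-hold durations.

    With a long enough hold, NO accumulated in the bronchial gas produces an
    early FE_NO maximum followed by a local minimum and a slow rise; the
    peak grows with the hold duration.
    """
    table = table if table is not None else load_morphometry()
    out: dict[float, SimulationResult] = {}
    for t_bh in t_bh_list:
        pattern = BreathingPattern.classical(t_bh=float(t_bh))
        out[float(t_bh)] = classical_cycle_experiment(table, pattern, **model_kwargs)
    return out


@dataclass(frozen=True)
class ComparisonMetrics:
    """Relative unhealthy-vs-healthy differences (see module docstring)."""

    d_feno50: float
    d_j: float
    d_flux: float
    last_constricted_generation: int
    beta: float
    mucus_cm: float
    start_generation: int
    feno50_healthy_ppb: float
    feno50_unhealthy_ppb: float


def _end_expiration_wall_flux(res: SimulationResult, generation: int,
                              wall_params: WallTransportParams):
    """(mean flux density, total flow) of the epithelium-to-lumen exchange in
    ``generation`` at the end of expiration."""
    model = res.model
    tr = res.expiration
    op = tr.operator
    s = op.s_of(tr.times[-1])
    rest = model.rest
    r_muc, r_lum, r_epi, r_mus = wall_radii_at_scale(rest, s)
    ha = hatta_numbers(r_mus[generation] - r_epi[generation],
                       r_epi[generation] - r_lum[generation],
                       r_lum[generation] - r_muc[generation], wall_params)
    law = airway_flux_law(ha, wall_params)
    c = res.field_at_end(Phase.EXPIRATION).per_generation(generation)
    j_mean = float(np.mean(law(c)))
    s_air = op.s_air_rest[generation] * np.sqrt(s)
    return j_mean, j_mean * s_air


def bc_experiment(
    last_constricted_generation: int,
    beta: float,
    mucus_thickness_cm: float = 0.0,
    start_generation: int = DEFAULT_START_GENERATION,
    table: MorphometryTable | None = None,
    pattern: BreathingPattern | None = None,
    healthy_result: SimulationResult | None = None,
    **model_kwargs,
) -> ComparisonMetrics:
    """Cumulative homogeneous bronchoconstriction experiment.

    Constricts generations ``start_generation..last_constricted_generation``
    at a common lumen-area reduction ``beta``, optionally coats generations
    0-18 with a mucus film (rest thickness before constriction), and compares
    the altered lungs against healthy lungs breathing the same pattern.  A
    precomputed ``healthy_result`` may be passed to avoid re-running the
    reference simulation across a sweep.
    """
    if not 0 < beta <= 1:
        raise ValueError("beta must lie in (0, 1]")
    table = table if table is not None else load_morphometry()
    pattern = pattern if pattern is not None else BreathingPattern.classical()
    wall_params = model_kwargs.get("wall_params", WallTransportParams())

    if healthy_result is None:
        healthy_result = simulate_cycle(healthy_model(table, pattern, **model_kwargs))

    walls = (WallLayerSpec.uniform_mucus(mucus_thickness_cm)
             if mucus_thickness_cm > 0 else WallLayerSpec())
    constriction = ConstrictionProfile.homogeneous_beta(
        beta, start_generation, last_constricted_generation)
    rest = apply_alterations(table, walls, constriction)
    model = replace(healthy_result.model, rest=rest, pattern=pattern, **model_kwargs)
    unhealthy_result = simulate_cycle(model)

    g = last_constricted_generation
    j_h, flux_h = _end_expiration_wall_flux(healthy_result, g, wall_params)
    j_u, flux_u = _end_expiration_wall_flux(unhealthy_result, g, wall_params)
    f_h = healthy_result.feno_end_ppb
    f_u = unhealthy_result.feno_end_ppb
    return ComparisonMetrics(
        d_feno50=(f_u - f_h) / f_h,
        d_j=(j_u - j_h) / j_h,
        d_flux=(flux_u - flux_h) / flux_h,
        last_constricted_generation=g,
        beta=beta,
        mucus_cm=mucus_thickness_cm,
        start_generation=start_generation,
        feno50_healthy_ppb=f_h,
        feno50_unhealthy_ppb=f_u,
    )


def wall_profile_report(
    result: SimulationResult,
    generation: int = 12,
    zeta: float = 1.0,
    wall_params: WallTransportParams | None = None,
    n_per_layer: int = 200,
) -> pd.DataFrame:
    """Wall concentration profiles at end-inspiration and end-expiration.

    Evaluates the analytic layered-wall profile of ``generation`` at axial
    position ``zeta``, using the simulated lumen concentration and the
    instantaneous layer thicknesses of each phase end.  The returned frame
    also reports the radial coordinate (distance to the airway centre).
    """
    wall_params = wall_params if wall_params is not None else WallTransportParams()
    frames = []
    for tr in result.phases:
        if tr.phase is Phase.BREATH_HOLD:
            continue
        op = tr.operator
        s = op.s_of(tr.times[-1])
        rest = result.model.rest
        r_muc, r_lum, r_epi, r_mus = wall_radii_at_scale(rest, s)
        sl = result.model.grid.node_slice(generation)
        c_gen = tr.final[sl]
        zetas = np.linspace(0, 1, len(c_gen))
        c_lumen = float(np.interp(zeta, zetas, c_gen))
        ha = hatta_numbers(r_mus[generation] - r_epi[generation],
                           r_epi[generation] - r_lum[generation],
                           r_lum[generation] - r_muc[generation], wall_params)
        prof = wall_profile(ha, wall_params, c_lumen)
        df = prof.sample(n_per_layer)
        # x runs blood->lumen; radial distance runs centre->outward
        df["r_cm"] = r_mus[generation] - df["x_cm"]
        df["phase"] = tr.phase.value
        df["C_lumen_ppb"] = c_lumen / PPB
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
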