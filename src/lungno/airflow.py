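"""Quasi-steady air flow distribution along the generation tree.

Incompressible flow with uniformly inflating cross-sections makes the air
flow quasi-steady: the flow rate entering a generation is depleted linearly
along it in proportion to the gas volume stored downstream.  With
``f_i = L_i Omega_i / V`` the volume fraction of generation ``i``,

    Q_i(zeta) = Q0 * (1 - sum_{j<i} f_j - f_i * zeta)

during inspiration (``Q0 = q_in``) and expiration (``Q0 = q_ex``), and
``Q_i = 0`` during breath-hold.  ``zeta = z / L_i`` is the dimensionless
axial position within the generation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cycle import BreathingPattern, Phase
from .morphometry import MorphometryTable, RestingLungGeometry

#: diffusion coefficient of NO in air at body conditions, cm^2/s
DEFAULT_D_NO_AIR = 0.217

__all__ = ["FlowField", "volume_fractions", "flow_profile", "peclet_numbers",
           "DEFAULT_D_NO_AIR"]


def volume_fractions(rest: RestingLungGeometry) -> np.ndarray:
    """Gas-volume share ``f_i = L_i Omega_i / V`` of each generation (sums to 1)."""
    return rest.volume_fractions


@dataclass(frozen=True)
class FlowField:
    """Air flow rate along the tree for one respiratory phase.

    ``q0`` is the mouth flow rate of the phase (ml/s, signed); ``fractions``
    the per-generation volume shares.  ``Q_i(zeta)`` is evaluated lazily.
    """

    phase: Phase
    q0: float
    fractions: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.fractions, dtype=float)
        if abs(f.sum() - 1.0) > 1e-12:
            raise ValueError("volume fractions must sum to 1")
        object.__setattr__(self, "fractions", f)

    def flow(self, generation: int | np.ndarray, zeta: float | np.ndarray) -> np.ndarray:
        """Flow rate ``Q_i(zeta)`` in ml/s (vectorised over zeta)."""
        upstream = np.concatenate(([0.0], np.cumsum(self.fractions)))[:-1]
        gen = np.asarray(generation)
        return self.q0 * (1.0 - upstream[gen] - self.fractions[gen] * np.asarray(zeta))


def flow_profile(fractions: np.ndarray, pattern: BreathingPattern, phase: Phase) -> FlowField:
    """Quasi-steady flow field of the given phase."""
    if not isinstance(phase, Phase):
        raise ValueError(f"unknown phase {phase!r}")
    return FlowField(phase=phase, q0=pattern.phase_flow(phase), fractions=fractions)


def peclet_numbers(
    geometry: MorphometryTable | RestingLungGeometry,
    q_in: float = 500.0,
    d_no_air: float = DEFAULT_D_NO_AIR,
) -> np.ndarray:
    """Per-generation axial Peclet number ``Pe_i = L_i q_in / (D_NO,air OmegaPrime_i)``.

    Ratio of the axial diffusion time ``L^2/D`` to the convective residence
    time ``OmegaPrime L / q_in``: ``Pe >> 1`` marks convection-dominated
    generations, ``Pe < 1`` diffusion-dominated ones.  Evaluated for the rest
    geometry (healthy table or post-alteration).
    """
    if q_in <= 0 or d_no_air <= 0:
        raise ValueError("flow rate and diffusivity must be positive")
    length = geometry.length if isinstance(geometry, RestingLungGeometry) else geometry.length
    return length * q_in / (d_no_air * geometry.omega_prime)


def flow_table(rest: RestingLungGeometry, pattern: BreathingPattern,
               q_in: float | None = None, d_no_air: float = DEFAULT_D_NO_AIR) -> pd.DataFrame:
    """Tabular export of per-generation volume fractions and Peclet numbers."""
    f = volume_fractions(rest)
    pe = peclet_numbers(rest, q_in if q_in is not None else pattern.q_in, d_no_air)
    return pd.DataFrame({
        "generation": np.arange(len(f)),
        "volume_fraction": f,
        "peclet": pe,
    })
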