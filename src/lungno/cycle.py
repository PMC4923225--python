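"""Respiratory-cycle kinematics: breathing pattern and time-varying geometry.

During a cycle the lungs inflate and deflate uniformly: every cross-section
scales by the same factor ``s`` while airway lengths stay fixed, so

* inspiration:  ``s(theta) = 1 + Dil * theta``, ``theta = t / t_in`` in [0, 1],
* breath-hold:  ``s = 1 + Dil`` (constant),
* expiration:   ``s(theta) = 1 + Dil * (1 - theta)``, ``theta = t / t_ex``,

where ``Dil = Q_in * t_in / V`` is the inspired volume relative to the
pre-inspiratory gas volume.  Airway radii scale as ``sqrt(s)``; the outer
wall radii follow from layer-area conservation at every instant.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .morphometry import LAST_WALLED_GENERATION, RestingLungGeometry

#: inner diameter of an alveolus, cm (treated as constant over the cycle)
DEFAULT_ALVEOLUS_DIAMETER_CM = 0.0200

__all__ = ["Phase", "BreathingPattern", "InstantGeometry", "instant_geometry",
           "scale_factor", "DEFAULT_ALVEOLUS_DIAMETER_CM"]


class Phase(str, enum.Enum):
    INSPIRATION = "inspiration"
    BREATH_HOLD = "breath-hold"
    EXPIRATION = "expiration"


@dataclass(frozen=True)
class BreathingPattern:
    """Flow rates and phase durations of one respiratory cycle.

    ``q_in`` (ml/s, > 0) and ``q_ex`` (ml/s, < 0) are the inspiratory and
    expiratory flow rates; pre- and post-cycle lung volumes must match, i.e.
    ``q_in * t_in = -q_ex * t_ex``.
    """

    q_in: float = 500.0
    q_ex: float = -50.0
    t_in: float = 2.0
    t_bh: float = 0.0
    t_ex: float = 20.0

    def __post_init__(self) -> None:
        if self.q_in <= 0:
            raise ValueError("inspiratory flow must be positive")
        if self.q_ex >= 0:
            raise ValueError("expiratory flow must be negative")
        if self.t_in <= 0 or self.t_ex <= 0 or self.t_bh < 0:
            raise ValueError("phase durations must be positive (breath-hold may be zero)")
        vin, vex = self.q_in * self.t_in, -self.q_ex * self.t_ex
        if abs(vin - vex) > 1e-9 * vin:
            raise ValueError(
                f"inspired volume {vin:.6g} ml != expired volume {vex:.6g} ml; "
                "adjust t_ex = q_in*t_in/|q_ex|"
            )

    @classmethod
    def classical(cls, **overrides) -> "BreathingPattern":
        """The standard FE_NO measurement maneuver: 500 ml/s inspiration for
        2 s, no breath-hold, 50 ml/s expiration for 20 s."""
        return cls(**overrides)

    @classmethod
    def with_expiratory_flow(cls, q_ex_abs: float, q_in: float = 500.0,
                             t_in: float = 2.0, t_bh: float = 0.0) -> "BreathingPattern":
        """Pattern with expiration duration adjusted to expire the inspired volume."""
        return cls(q_in=q_in, q_ex=-abs(q_ex_abs), t_in=t_in, t_bh=t_bh,
                   t_ex=q_in * t_in / abs(q_ex_abs))

    def dil(self, rest: RestingLungGeometry) -> float:
        """Dimensionless dilation number ``Dil = q_in t_in / V``."""
        return self.q_in * self.t_in / rest.total_volume

    def phase_duration(self, phase: Phase) -> float:
        return {Phase.INSPIRATION: self.t_in, Phase.BREATH_HOLD: self.t_bh,
                Phase.EXPIRATION: self.t_ex}[phase]

    def phase_flow(self, phase: Phase) -> float:
        return {Phase.INSPIRATION: self.q_in, Phase.BREATH_HOLD: 0.0,
                Phase.EXPIRATION: self.q_ex}[phase]


def scale_factor(phase: Phase, theta: float, dil: float, t_bh_over_t_in: float = 0.0) -> float:
    """Uniform cross-section scaling ``s = Omega_i(theta)/Omega_i`` for a phase.

    ``theta`` is the dimensionless phase time: t/t_in for inspiration and
    breath-hold, t/t_ex for expiration.
    """
    if phase is Phase.INSPIRATION:
        if not 0.0 <= theta <= 1.0 + 1e-12:
            raise ValueError(f"inspiration theta must be in [0, 1], got {theta}")
        return 1.0 + dil * theta
    if phase is Phase.BREATH_HOLD:
        if not 0.0 <= theta <= t_bh_over_t_in + 1e-12:
            raise ValueError(f"breath-hold theta must be in [0, {t_bh_over_t_in}], got {theta}")
        return 1.0 + dil
    if phase is Phase.EXPIRATION:
        if not 0.0 <= theta <= 1.0 + 1e-12:
            raise ValueError(f"expiration theta must be in [0, 1], got {theta}")
        return 1.0 + dil * (1.0 - theta)
    raise ValueError(f"unknown phase {phase!r}")


@dataclass(frozen=True)
class InstantGeometry:
    """Geometry of the lungs at one instant of a respiratory cycle.

    Cross-sections are inflated by the uniform factor ``scale``; the inner
    gas-facing radius scales as ``sqrt(scale)`` and the remaining wall radii
    follow from annular-area conservation.  Exchange surfaces:
    ``S_air,i = 2**i * 2 pi R_mu,i(theta) L_i`` (generations 0-18, airway
    wall to lumen) and ``S_alv,i = Omega_alv,i(theta) L_i * 6 / d_alv``
    (hemispherical alveoli).
    """

    phase: Phase
    theta: float
    scale: float
    rest: RestingLungGeometry
    omega: np.ndarray
    omega_prime: np.ndarray
    r_mucus: np.ndarray
    r_lumen: np.ndarray
    r_epithelium: np.ndarray
    r_muscle: np.ndarray
    s_air: np.ndarray
    s_alv: np.ndarray
    d_alv: float

    @property
    def delta_mucus(self) -> np.ndarray:
        return self.r_lumen - self.r_mucus

    @property
    def delta_epithelium(self) -> np.ndarray:
        return self.r_epithelium - self.r_lumen

    @property
    def delta_muscle(self) -> np.ndarray:
        return self.r_muscle - self.r_epithelium

    @property
    def total_volume(self) -> float:
        return float(np.sum(self.omega * self.rest.length))

    @property
    def s_alv_total(self) -> float:
        return float(self.s_alv.sum())


def wall_radii_at_scale(rest: RestingLungGeometry, scale: float):
    """Wall radii of generations 0-18 when cross-sections are scaled by ``scale``.

    With ``R_mu(theta) = sqrt(scale) R_mu``, area conservation of each layer
    gives ``R_x(theta) = sqrt(R_x**2 + (scale - 1) R_mu**2)`` for the lumen,
    epithelium and muscle radii.
    """
    shift = (scale - 1.0) * rest.r_mucus**2
    r_muc = np.sqrt(scale) * rest.r_mucus
    r_lum = np.sqrt(rest.r_lumen**2 + shift)
    r_epi = np.sqrt(rest.r_epithelium**2 + shift)
    r_mus = np.sqrt(rest.r_muscle**2 + shift)
    return r_muc, r_lum, r_epi, r_mus


def instant_geometry(
    rest: RestingLungGeometry,
    pattern: BreathingPattern,
    phase: Phase,
    theta: float,
    d_alv: float = DEFAULT_ALVEOLUS_DIAMETER_CM,
) -> InstantGeometry:
    """Geometry at dimensionless time ``theta`` of the given phase."""
    dil = pattern.dil(rest)
    s = scale_factor(phase, theta, dil, pattern.t_bh / pattern.t_in)
    r_muc, r_lum, r_epi, r_mus = wall_radii_at_scale(rest, s)
    n = LAST_WALLED_GENERATION + 1
    i = np.arange(n)
    s_air = np.zeros(len(rest.length))
    s_air[:n] = 2.0**i * 2.0 * np.pi * r_muc * rest.length[:n]
    s_alv = rest.omega_alv * s * rest.length * 6.0 / d_alv
    return InstantGeometry(
        phase=phase,
        theta=theta,
        scale=s,
        rest=rest,
        omega=rest.omega * s,
        omega_prime=rest.omega_prime * s,
        r_mucus=r_muc,
        r_lumen=r_lum,
        r_epithelium=r_epi,
        r_muscle=r_mus,
        s_air=s_air,
        s_alv=s_alv,
        d_alv=d_alv,
    )
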