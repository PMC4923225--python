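"""Static lung morphometry and its remodeling by bronchoconstriction and mucus.

The lungs are represented as 24 generations (0 = trachea, 23 = terminal
alveolated ducts) of a symmetric dichotomously branching tree, following the
Weibel morphometric model.  Generation ``i`` holds ``2**i`` identical airways
of length ``L_i``.  Two cross-sections characterise a generation:

* ``Omega_i`` (cm^2): total cross-section, such that ``Omega_i * L_i`` is the
  whole gas volume of the generation (lumen plus alveoli);
* ``OmegaPrime_i`` (cm^2): flow cross-section, counting the lumen only, the
  part through which axial transport occurs.

For generations 0-18 the airway wall is resolved as concentric layers:
epithelium (inner), smooth muscle (outer), and optionally a mucus film lining
the epithelium.  Bronchoconstriction is modeled as an axisymmetric reduction
of the airway caliber at conserved tissue volume: when the outer muscle
radius shrinks, every layer thickens so that each annular area is preserved.

All lengths are in cm, areas in cm^2, volumes in cm^3 (= ml).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

N_GENERATIONS = 24
#: last generation with a layered (epithelium/muscle/mucus) wall
LAST_WALLED_GENERATION = 18
#: default layer thicknesses of the unconstricted wall, cm
DEFAULT_EPITHELIUM_CM = 0.0015
DEFAULT_MUSCLE_CM = 0.0030

__all__ = [
    "MorphometryTable",
    "WallLayerSpec",
    "ConstrictionProfile",
    "RestingLungGeometry",
    "load_morphometry",
    "rest_radii",
    "alpha_max",
    "beta_to_alpha",
    "alpha_to_beta",
    "apply_alterations",
    "N_GENERATIONS",
    "LAST_WALLED_GENERATION",
]


class MorphometryError(ValueError):
    """Raised when a morphometric table or an alteration request is invalid."""


@dataclass(frozen=True)
class MorphometryTable:
    """Per-generation static anatomy of healthy lungs at rest.

    Attributes
    ----------
    length : (24,) array, airway length ``L_i`` in cm.
    omega : (24,) array, total cross-section ``Omega_i,0`` in cm^2.
    omega_prime : (24,) array, flow (lumen) cross-section ``OmegaPrime_i,0``.
    """

    length: np.ndarray
    omega: np.ndarray
    omega_prime: np.ndarray

    def __post_init__(self) -> None:
        for name in ("length", "omega", "omega_prime"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
            if arr.shape != (N_GENERATIONS,):
                raise MorphometryError(
                    f"{name}: expected {N_GENERATIONS} generations, got {arr.shape}"
                )
        if np.any(self.length <= 0):
            bad = int(np.flatnonzero(self.length <= 0)[0])
            raise MorphometryError(f"generation {bad}: non-positive length")
        if np.any(self.omega_prime <= 0):
            bad = int(np.flatnonzero(self.omega_prime <= 0)[0])
            raise MorphometryError(f"generation {bad}: non-positive flow cross-section")
        if np.any(self.omega < self.omega_prime - 1e-12):
            bad = int(np.flatnonzero(self.omega < self.omega_prime - 1e-12)[0])
            raise MorphometryError(
                f"generation {bad}: total cross-section smaller than flow cross-section"
            )

    @property
    def omega_alv(self) -> np.ndarray:
        """Alveolar cross-section ``Omega_alv,i,0 = Omega_i,0 - OmegaPrime_i,0``."""
        return self.omega - self.omega_prime

    @property
    def total_volume(self) -> float:
        """Total gas volume of healthy lungs at rest, ``V_0 = sum Omega_i,0 L_i`` (ml)."""
        return float(np.sum(self.omega * self.length))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "generation": np.arange(N_GENERATIONS),
                "L_cm": self.length,
                "Omega_cm2": self.omega,
                "OmegaPrime_cm2": self.omega_prime,
                "OmegaAlv_cm2": self.omega_alv,
            }
        )


def load_morphometry(source: str | Path | None = None) -> MorphometryTable:
    """Load a morphometric table from CSV (packaged Weibel table by default).

    The CSV must contain columns ``generation``, ``L_cm``, ``Omega_cm2`` and
    ``OmegaPrime_cm2`` with one row per generation 0-23.
    """
    if source is None:
        with resources.files("lungno.data").joinpath("weibel_morphometry.csv").open() as fh:
            df = pd.read_csv(fh)
    else:
        df = pd.read_csv(source)
    required = {"generation", "L_cm", "Omega_cm2", "OmegaPrime_cm2"}
    missing = required - set(df.columns)
    if missing:
        raise MorphometryError(f"missing columns: {sorted(missing)}")
    df = df.sort_values("generation")
    gens = df["generation"].to_numpy()
    if len(gens) != N_GENERATIONS or not np.array_equal(gens, np.arange(N_GENERATIONS)):
        raise MorphometryError(
            f"expected generations 0..{N_GENERATIONS - 1}, got {len(gens)} rows"
        )
    return MorphometryTable(
        length=df["L_cm"].to_numpy(float),
        omega=df["Omega_cm2"].to_numpy(float),
        omega_prime=df["OmegaPrime_cm2"].to_numpy(float),
    )


@dataclass(frozen=True)
class WallLayerSpec:
    """Rest thicknesses of the airway-wall layers (generations 0-18).

    ``epithelium_cm`` and ``muscle_cm`` are generation-independent; the mucus
    film ``mucus_cm`` may vary per generation and must vanish for
    generations 19-23, whose walls are made of alveoli and carry no mucus.
    """

    epithelium_cm: float = DEFAULT_EPITHELIUM_CM
    muscle_cm: float = DEFAULT_MUSCLE_CM
    mucus_cm: np.ndarray = field(default_factory=lambda: np.zeros(N_GENERATIONS))

    def __post_init__(self) -> None:
        mucus = np.asarray(self.mucus_cm, dtype=float)
        if mucus.ndim == 0:
            thick = float(mucus)
            mucus = np.zeros(N_GENERATIONS)
            mucus[: LAST_WALLED_GENERATION + 1] = thick
        if mucus.shape != (N_GENERATIONS,):
            raise MorphometryError("mucus_cm must be scalar or have one value per generation")
        object.__setattr__(self, "mucus_cm", mucus)
        if self.epithelium_cm <= 0 or self.muscle_cm <= 0:
            raise MorphometryError("epithelium and muscle thicknesses must be positive")
        if np.any(mucus < 0):
            raise MorphometryError("mucus thickness cannot be negative")
        if np.any(mucus[LAST_WALLED_GENERATION + 1 :] > 0):
            raise MorphometryError("no mucus can be present in generations 19-23")

    @classmethod
    def uniform_mucus(cls, thickness_cm: float, first: int = 0,
                      last: int = LAST_WALLED_GENERATION,
                      epithelium_cm: float = DEFAULT_EPITHELIUM_CM,
                      muscle_cm: float = DEFAULT_MUSCLE_CM) -> "WallLayerSpec":
        """Coat generations ``first..last`` with a uniform mucus film."""
        mucus = np.zeros(N_GENERATIONS)
        mucus[first : last + 1] = thickness_cm
        return cls(epithelium_cm=epithelium_cm, muscle_cm=muscle_cm, mucus_cm=mucus)


@dataclass(frozen=True)
class RestRadii:
    """Unconstricted per-airway rest radii for generations 0-18 (cm).

    ``r_mucus <= r_lumen < r_epithelium < r_muscle``; ``r_lumen`` is the inner
    epithelial radius, ``r_mucus`` the gas-facing radius once a mucus film is
    present.  Arrays have length 19 (generations 0-18).
    """

    r_mucus: np.ndarray
    r_lumen: np.ndarray
    r_epithelium: np.ndarray
    r_muscle: np.ndarray


def rest_radii(table: MorphometryTable, walls: WallLayerSpec) -> RestRadii:
    """Per-airway wall radii of the unconstricted lungs at rest.

    The lumen radius follows from the flow cross-section shared by ``2**i``
    axisymmetric airways, ``R_L = sqrt(OmegaPrime_i,0 / (pi 2**i))``; the
    epithelial and muscle radii add the rest layer thicknesses, and a mucus
    film subtracts from the gas side.
    """
    n = LAST_WALLED_GENERATION + 1
    i = np.arange(n)
    r_lumen = np.sqrt(table.omega_prime[:n] / (np.pi * 2.0**i))
    r_epi = r_lumen + walls.epithelium_cm
    r_mus = r_epi + walls.muscle_cm
    r_muc = r_lumen - walls.mucus_cm[:n]
    if np.any(r_muc <= 0):
        bad = int(np.flatnonzero(r_muc <= 0)[0])
        raise MorphometryError(f"generation {bad}: mucus film would occlude the lumen")
    return RestRadii(r_mucus=r_muc, r_lumen=r_lumen, r_epithelium=r_epi, r_muscle=r_mus)


def alpha_max(radii: RestRadii) -> np.ndarray:
    """Maximum outer-radius constriction fraction before lumen occlusion.

    ``alpha_max = 1 - sqrt(1 - (R_mu,0 / R_M,0)**2)``: at this level the
    conserved-volume layers fill the whole airway and the gas passage closes.
    """
    return 1.0 - np.sqrt(1.0 - (radii.r_mucus / radii.r_muscle) ** 2)


def beta_to_alpha(beta: np.ndarray | float, radii: RestRadii) -> np.ndarray:
    """Convert lumen-area reduction ``beta`` to outer-radius reduction ``alpha``.

    ``beta = 1 - R_mu**2 / R_mu,0**2`` measures the relative loss of lumen
    cross-section; ``alpha = 1 - sqrt(1 - (R_mu,0/R_M,0)**2 beta)``.
    ``beta = 1`` maps exactly onto ``alpha_max``.
    """
    beta = np.asarray(beta, dtype=float)
    if np.any((beta < 0) | (beta > 1)):
        raise MorphometryError("beta must lie in [0, 1]")
    return 1.0 - np.sqrt(1.0 - (radii.r_mucus / radii.r_muscle) ** 2 * beta)


def alpha_to_beta(alpha: np.ndarray | float, radii: RestRadii) -> np.ndarray:
    """Inverse of :func:`beta_to_alpha`."""
    alpha = np.asarray(alpha, dtype=float)
    return (1.0 - (1.0 - alpha) ** 2) * (radii.r_muscle / radii.r_mucus) ** 2


@dataclass(frozen=True)
class ConstrictionProfile:
    """Per-generation bronchoconstriction level for generations 0-18.

    Expressed either as ``alpha`` (outer-radius reduction fraction) or as
    ``beta`` (lumen-area reduction fraction); the two are interconvertible
    against a set of rest radii.  Generations 19-23 cannot constrict.
    """

    alpha: np.ndarray | None = None
    beta: np.ndarray | None = None

    def __post_init__(self) -> None:
        if (self.alpha is None) == (self.beta is None):
            raise MorphometryError("give exactly one of alpha or beta")
        name = "alpha" if self.alpha is not None else "beta"
        arr = np.asarray(getattr(self, name), dtype=float)
        n = LAST_WALLED_GENERATION + 1
        if arr.shape != (n,):
            raise MorphometryError(f"{name} must have {n} entries (generations 0-18)")
        if np.any(arr < 0) or (name == "beta" and np.any(arr > 1)):
            raise MorphometryError(f"{name} out of range")
        object.__setattr__(self, name, arr)

    @classmethod
    def none(cls) -> "ConstrictionProfile":
        return cls(alpha=np.zeros(LAST_WALLED_GENERATION + 1))

    @classmethod
    def homogeneous_beta(cls, beta: float, first: int, last: int) -> "ConstrictionProfile":
        """Homogeneous constriction of generations ``first..last`` at level ``beta``."""
        if not 0 <= first <= last <= LAST_WALLED_GENERATION:
            raise MorphometryError("constricted range must lie within generations 0-18")
        arr = np.zeros(LAST_WALLED_GENERATION + 1)
        arr[first : last + 1] = beta
        return cls(beta=arr)

    def resolve_alpha(self, radii: RestRadii) -> np.ndarray:
        return self.alpha if self.alpha is not None else beta_to_alpha(self.beta, radii)


@dataclass(frozen=True)
class RestingLungGeometry:
    """Lungs at rest after possible alteration by constriction and/or mucus.

    Wall radii and thickness arrays cover generations 0-18 only (distal
    generations have no layered wall); cross-sections cover all 24.
    """

    table: MorphometryTable
    walls: WallLayerSpec
    r_mucus: np.ndarray
    r_lumen: np.ndarray
    r_epithelium: np.ndarray
    r_muscle: np.ndarray
    omega: np.ndarray
    omega_prime: np.ndarray

    @property
    def length(self) -> np.ndarray:
        return self.table.length

    @property
    def omega_alv(self) -> np.ndarray:
        return self.table.omega_alv

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
        """Total gas volume ``V = sum Omega_i L_i`` of the altered rest lungs (ml)."""
        return float(np.sum(self.omega * self.table.length))

    @property
    def volume_fractions(self) -> np.ndarray:
        """``f_i = L_i Omega_i / V``, the gas-volume share of each generation."""
        v = self.omega * self.table.length
        return v / v.sum()


def apply_alterations(
    table: MorphometryTable,
    walls: WallLayerSpec | None = None,
    constriction: ConstrictionProfile | None = None,
) -> RestingLungGeometry:
    """Build the resting geometry of possibly constricted, mucus-coated lungs.

    Constriction shrinks the outer muscle radius by ``alpha`` while each
    annular layer (muscle, epithelium, mucus) keeps its cross-sectional area,
    so the inner radii follow ``R_x = sqrt(R_x,0**2 + ((1-alpha)**2 - 1) R_M,0**2)``.
    The flow cross-section becomes ``OmegaPrime_i = 2**i pi R_mu,i**2`` for
    generations 0-18; alveolar volumes are untouched.
    """
    walls = walls if walls is not None else WallLayerSpec()
    constriction = constriction if constriction is not None else ConstrictionProfile.none()
    radii0 = rest_radii(table, walls)
    alpha = constriction.resolve_alpha(radii0)
    amax = alpha_max(radii0)
    if np.any(alpha > amax + 1e-12):
        bad = int(np.flatnonzero(alpha > amax + 1e-12)[0])
        raise MorphometryError(
            f"generation {bad}: alpha={alpha[bad]:.4f} exceeds alpha_max={amax[bad]:.4f} "
            "(radicand negative, lumen would be occluded)"
        )
    shift = ((1.0 - alpha) ** 2 - 1.0) * radii0.r_muscle**2
    r_mus = (1.0 - alpha) * radii0.r_muscle
    r_epi = np.sqrt(radii0.r_epithelium**2 + shift)
    r_lum = np.sqrt(radii0.r_lumen**2 + shift)
    r_muc = np.sqrt(np.maximum(radii0.r_mucus**2 + shift, 0.0))

    n = LAST_WALLED_GENERATION + 1
    omega_prime = table.omega_prime.copy()
    omega_prime[:n] = 2.0 ** np.arange(n) * np.pi * r_muc**2
    omega = omega_prime + table.omega_alv
    return RestingLungGeometry(
        table=table,
        walls=walls,
        r_mucus=r_muc,
        r_lumen=r_lum,
        r_epithelium=r_epi,
        r_muscle=r_mus,
        omega=omega,
        omega_prime=omega_prime,
    )
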