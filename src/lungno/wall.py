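"""NO exchange between airway walls / alveoli and the gas in the lumen.

Airway wall (generations 0-18)
------------------------------
The wall is a stack of up to three layers crossed by a coordinate ``x``
pointing from the blood-muscle interface (``x = 0``) toward the lumen:
muscle (thickness ``dM``), epithelium (``dE``), optional mucus (``dmu``).
NO diffuses through the layers with diffusivity ``D`` (as in liquid water),
is produced volumetrically in the epithelium at rate ``Pr`` and consumed in
both tissue layers by a first-order reaction of constant ``k``; the mucus is
inert.  Quasi-steady, planar transport gives

    D C_E'' + Pr - k C_E = 0,     D C_M'' - k C_M = 0,     C_mu'' = 0,

with a perfect blood sink ``C_M(0) = 0`` (hemoglobin scavenging), continuity
of concentration and diffusive flux at the internal interfaces, and Henry
equilibrium with the lumen, ``C_mu(top) = lambda * C``.

With ``m = sqrt(k/D)`` the layers are governed by the Hatta numbers
``Ha = m dM``, ``Ha~ = m dE`` and the mucus film number ``Mu = m dmu``.
Solving the system in hyperbolic functions yields the affine flux law
``J_air(C) = a - b C`` (per unit lumen surface, gas-phase units) with

    den = sinh(Ha + Ha~) + Mu cosh(Ha + Ha~)
    a = gamma Pr sqrt(D/k) (cosh(Ha + Ha~) - cosh Ha) / den
    b = gamma lambda sqrt(k D) cosh(Ha + Ha~) / den

``gamma`` (cm^3/mol) converts molar tissue concentrations into gas volumes.
A numerical two-point boundary-value oracle and a transient axisymmetric
cylindrical solver are provided to validate the planar quasi-steady law.

Alveolar walls
--------------
The alveolar exchange is lumped:
``J_alv(C) = P_alv / S_alv,tot - (U_alv / S_alv,tot) C``; its equilibrium
``P_alv / U_alv`` is the 2-3 ppb alveolar NO plateau.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.integrate import solve_ivp

__all__ = [
    "WallTransportParams", "AlveolarParams", "HattaNumbers", "FluxLaw",
    "WallProfile", "hatta_numbers", "airway_flux_law", "alveolar_flux_law",
    "wall_profile", "fraction_consumed", "slab_flux_numerical",
    "transient_cylindrical_wall", "TransientWallResult",
]

GAS_CONSTANT = 82.057338  # cm^3 atm / (mol K)
BODY_TEMPERATURE_K = 310.15


@dataclass(frozen=True)
class WallTransportParams:
    """Transport and reaction parameters of the airway-wall tissue.

    d_no_t : NO diffusivity in tissue (taken as in liquid water), cm^2/s.
    k : first-order NO consumption rate constant in tissue, 1/s.
    pr : volumetric NO production rate in the epithelium, mol/(cm^3 s);
         the same value in every generation.
    lambda_t_air : Henry partition, mol NO per cm^3 tissue at unit gas
         volume fraction.
    gamma : molar volume of the gas, cm^3/mol; the tabulated default is the
         ideal-gas value at 37 degC and 1 atm.
    """

    d_no_t: float = 3.3e-5
    k: float = 2.001
    pr: float = 5.17e-12
    lambda_t_air: float = 1.64e-6
    gamma: float = 2.545e4

    def __post_init__(self) -> None:
        if min(self.d_no_t, self.k, self.pr, self.lambda_t_air, self.gamma) <= 0:
            raise ValueError("all wall transport parameters must be positive")

    @property
    def m(self) -> float:
        """Reaction-diffusion length scale inverse ``sqrt(k/D)``, 1/cm."""
        return float(np.sqrt(self.k / self.d_no_t))


@dataclass(frozen=True)
class AlveolarParams:
    """Lumped alveolar NO source: total production ``p_alv`` (ml NO/s) and
    consumption conductance ``u_alv`` (cm^3 air/s)."""

    p_alv: float = 3.167e-6
    u_alv: float = 1558.0

    def __post_init__(self) -> None:
        if self.p_alv <= 0 or self.u_alv <= 0:
            raise ValueError("alveolar parameters must be positive")

    @property
    def equilibrium(self) -> float:
        """Alveolar equilibrium NO volume fraction ``p_alv/u_alv`` (~2 ppb)."""
        return self.p_alv / self.u_alv


@dataclass(frozen=True)
class HattaNumbers:
    """Dimensionless layer moduli ``sqrt(k/D) * thickness`` (vectorisable).

    ``ha`` for the muscle layer, ``ha_tilde`` for the epithelium, ``mu`` for
    the (inert) mucus film.
    """

    ha: np.ndarray | float
    ha_tilde: np.ndarray | float
    mu: np.ndarray | float = 0.0


def hatta_numbers(
    delta_muscle: np.ndarray | float,
    delta_epithelium: np.ndarray | float,
    delta_mucus: np.ndarray | float = 0.0,
    params: WallTransportParams | None = None,
) -> HattaNumbers:
    """Hatta numbers of a wall of given layer thicknesses (cm)."""
    p = params if params is not None else WallTransportParams()
    return HattaNumbers(
        ha=p.m * np.asarray(delta_muscle, float),
        ha_tilde=p.m * np.asarray(delta_epithelium, float),
        mu=p.m * np.asarray(delta_mucus, float),
    )


@dataclass(frozen=True)
class FluxLaw:
    """Affine exchange law ``J(C) = a - b C``.

    ``a``: production flux at zero lumen concentration, ml NO/(s cm^2);
    ``b``: consumption conductance, cm/s; ``C`` is a gas volume fraction.
    """

    a: np.ndarray | float
    b: np.ndarray | float

    def __call__(self, c: np.ndarray | float) -> np.ndarray | float:
        return self.a - self.b * c

    @property
    def equilibrium(self) -> np.ndarray | float:
        """Concentration ``C* = a/b`` at which the net exchange vanishes."""
        return self.a / self.b


def airway_flux_law(ha: HattaNumbers, params: WallTransportParams | None = None) -> FluxLaw:
    """Closed-form flux law of the layered airway wall (see module docstring).

    The mucus-free case is the exact ``Mu -> 0`` limit of the same
    expression, so both cases share one code path.
    """
    p = params if params is not None else WallTransportParams()
    h, ht, mu = (np.asarray(v, float) for v in (ha.ha, ha.ha_tilde, ha.mu))
    if np.any((h <= 0) & (ht <= 0) & (mu <= 0)):
        raise ValueError("degenerate wall: all layer thicknesses are zero")
    tot = h + ht
    den = np.sinh(tot) + mu * np.cosh(tot)
    a = p.gamma * p.pr * np.sqrt(p.d_no_t / p.k) * (np.cosh(tot) - np.cosh(h)) / den
    b = p.gamma * p.lambda_t_air * np.sqrt(p.k * p.d_no_t) * np.cosh(tot) / den
    return FluxLaw(a=a, b=b)


def alveolar_flux_law(alv: AlveolarParams, s_alv_total: float) -> FluxLaw:
    """Alveolar flux law per unit alveolar surface at total surface ``s_alv_total``."""
    if s_alv_total <= 0:
        raise ValueError("total alveolar surface must be positive")
    return FluxLaw(a=alv.p_alv / s_alv_total, b=alv.u_alv / s_alv_total)


@dataclass(frozen=True)
class WallProfile:
    """Piecewise analytic NO concentration across one airway wall.

    ``x`` runs from 0 at the blood-muscle interface to the lumen surface at
    ``delta_muscle + delta_epithelium + delta_mucus``.  Concentrations are in
    mol per cm^3 of layer.  The hyperbolic coefficients are:
    muscle ``A sinh(m x)``; epithelium ``Pr/k + B cosh(m(x-dM)) +
    F sinh(m(x-dM))``; mucus linear ``G + H (x - dM - dE)``.
    """

    delta_muscle: float
    delta_epithelium: float
    delta_mucus: float
    c_lumen: float
    params: WallTransportParams
    coef_a: float = field(repr=False, default=0.0)
    coef_b: float = field(repr=False, default=0.0)
    coef_f: float = field(repr=False, default=0.0)
    coef_g: float = field(repr=False, default=0.0)
    coef_h: float = field(repr=False, default=0.0)

    @property
    def thickness(self) -> float:
        return self.delta_muscle + self.delta_epithelium + self.delta_mucus

    def concentration(self, x: np.ndarray | float) -> np.ndarray:
        """NO concentration at depth ``x`` (mol/cm^3), vectorised."""
        x = np.asarray(x, float)
        p = self.params
        m = p.m
        dm, de = self.delta_muscle, self.delta_epithelium
        out = np.empty_like(x)
        in_m = x <= dm
        in_e = (x > dm) & (x <= dm + de)
        in_mu = x > dm + de
        out[in_m] = self.coef_a * np.sinh(m * x[in_m])
        xe = x[in_e] - dm
        out[in_e] = p.pr / p.k + self.coef_b * np.cosh(m * xe) + self.coef_f * np.sinh(m * xe)
        out[in_mu] = self.coef_g + self.coef_h * (x[in_mu] - dm - de)
        return out

    @property
    def flux_to_lumen(self) -> float:
        """Gas-phase flux density leaving the wall toward the lumen,
        ``-gamma D dC/dx`` at the lumen surface (ml NO / s / cm^2)."""
        return -self.params.gamma * self.params.d_no_t * self.coef_h

    @property
    def flux_to_blood(self) -> float:
        """Gas-phase flux density leaving the wall toward the blood,
        ``+gamma D dC/dx`` at x = 0."""
        p = self.params
        return p.gamma * p.d_no_t * p.m * self.coef_a

    @property
    def produced(self) -> float:
        """Total gas-phase production per unit wall surface, ``gamma Pr dE``."""
        p = self.params
        return p.gamma * p.pr * self.delta_epithelium

    @property
    def consumed(self) -> float:
        """Gas-phase consumption in the wall per unit surface (balance residue)."""
        return self.produced - self.flux_to_lumen - self.flux_to_blood

    def sample(self, n: int = 200) -> pd.DataFrame:
        """Evaluate the profile on ``n`` points per layer for export."""
        xs, layers = [], []
        bounds = [(0.0, self.delta_muscle, "muscle"),
                  (self.delta_muscle, self.delta_muscle + self.delta_epithelium, "epithelium")]
        if self.delta_mucus > 0:
            bounds.append((self.delta_muscle + self.delta_epithelium, self.thickness, "mucus"))
        for lo, hi, name in bounds:
            x = np.linspace(lo, hi, n)
            xs.append(x)
            layers.extend([name] * n)
        x = np.concatenate(xs)
        return pd.DataFrame({"x_cm": x, "layer": layers,
                             "C_mol_per_cm3": self.concentration(x)})


def wall_profile(
    ha: HattaNumbers,
    params: WallTransportParams | None = None,
    c_lumen: float = 0.0,
) -> WallProfile:
    """Analytic steady concentration profile across one wall.

    ``c_lumen`` is the NO volume fraction in the lumen gas.  The boundary
    flux of the returned profile reproduces :func:`airway_flux_law` exactly.
    """
    if c_lumen < 0:
        raise ValueError("lumen concentration cannot be negative")
    p = params if params is not None else WallTransportParams()
    h = float(np.asarray(ha.ha))
    ht = float(np.asarray(ha.ha_tilde))
    mu = float(np.asarray(ha.mu))
    m = p.m
    pk = p.pr / p.k
    tot = h + ht
    den = np.sinh(tot) + mu * np.cosh(tot)
    A = (p.lambda_t_air * c_lumen + pk * (np.cosh(ht) + mu * np.sinh(ht) - 1.0)) / den
    B = A * np.sinh(h) - pk
    F = A * np.cosh(h)
    G = pk * (1.0 - np.cosh(ht)) + A * np.sinh(tot)
    H = m * (A * np.cosh(tot) - pk * np.sinh(ht))
    return WallProfile(
        delta_muscle=h / m, delta_epithelium=ht / m, delta_mucus=mu / m,
        c_lumen=c_lumen, params=p,
        coef_a=float(A), coef_b=float(B), coef_f=float(F),
        coef_g=float(G), coef_h=float(H),
    )


def fraction_consumed(
    ha: HattaNumbers,
    params: WallTransportParams | None = None,
    c_lumen: float = 0.0,
) -> float:
    """Fraction of the epithelial NO production consumed within the wall.

    ``1 - (flux to lumen + flux to blood) / (Pr dE gamma)``; about 10 % for
    the healthy rest wall and up to ~25 % after strong constriction.
    """
    prof = wall_profile(ha, params, c_lumen)
    return prof.consumed / prof.produced


# ---------------------------------------------------------------------------
# numerical oracles
# ---------------------------------------------------------------------------

def _slab_flux_fd(ha: HattaNumbers, params: WallTransportParams, c_lumen: float,
                  n: int) -> float:
    """Second-order finite-difference solve of the layered-slab problem;
    returns the gas-phase flux density to the lumen."""
    p = params
    m = p.m
    dm, de, dmu = float(np.asarray(ha.ha)) / m, float(np.asarray(ha.ha_tilde)) / m, \
        float(np.asarray(ha.mu)) / m
    layers = [(dm, True, 0.0), (de, True, p.pr)]
    if dmu > 0:
        layers.append((dmu, False, 0.0))
    # global grid: n intervals per layer, shared interface nodes
    sizes = [n + 1] * len(layers)
    total = sum(sizes) - (len(layers) - 1)
    rows, cols, vals, rhs = [], [], [], np.zeros(total)

    def add(r, c, v):
        rows.append(r); cols.append(c); vals.append(v)

    offset = 0
    hs = [thick / n for thick, _, _ in layers]
    for li, (thick, reactive, prod) in enumerate(layers):
        h = hs[li]
        for j in range(1, n):
            g = offset + j
            add(g, g - 1, p.d_no_t / h**2)
            add(g, g + 1, p.d_no_t / h**2)
            add(g, g, -2.0 * p.d_no_t / h**2 - (p.k if reactive else 0.0))
            rhs[g] = -prod
        offset += n
    # blood boundary
    add(0, 0, 1.0)
    rhs[0] = 0.0
    # interface nodes: second-order one-sided flux continuity
    offset = 0
    for li in range(len(layers) - 1):
        g = offset + n
        hl, hr = hs[li], hs[li + 1]
        add(g, g, 3.0 / (2 * hl) + 3.0 / (2 * hr))
        add(g, g - 1, -4.0 / (2 * hl))
        add(g, g - 2, 1.0 / (2 * hl))
        add(g, g + 1, -4.0 / (2 * hr))
        add(g, g + 2, 1.0 / (2 * hr))
        rhs[g] = 0.0
        offset += n
    # lumen boundary: Henry equilibrium with the gas
    add(total - 1, total - 1, 1.0)
    rhs[total - 1] = p.lambda_t_air * c_lumen
    mat = sp.csr_matrix((vals, (rows, cols)), shape=(total, total))
    c = spla.spsolve(mat, rhs)
    h = hs[-1]
    dcdx = (3.0 * c[-1] - 4.0 * c[-2] + c[-3]) / (2.0 * h)
    return -p.gamma * p.d_no_t * dcdx


def slab_flux_numerical(
    ha: HattaNumbers,
    params: WallTransportParams | None = None,
    c_lumen: float = 0.0,
    n: int = 2000,
) -> float:
    """Independent boundary-value oracle for the wall flux.

    Solves the quasi-steady layered diffusion-reaction problem with a
    second-order scheme at ``n`` and ``2n`` nodes per layer and Richardson-
    extrapolates the lumen-side flux.
    """
    p = params if params is not None else WallTransportParams()
    f1 = _slab_flux_fd(ha, p, c_lumen, n)
    f2 = _slab_flux_fd(ha, p, c_lumen, 2 * n)
    return f2 + (f2 - f1) / 3.0


@dataclass(frozen=True)
class TransientWallResult:
    """Outcome of the transient axisymmetric cylindrical wall simulation.

    ``settle_time`` is the first instant after which the lumen-side flux
    stays within 5 % of its remaining transient amplitude around the plateau;
    ``relaxation_time`` is the exponential time constant of the flux decay
    toward the plateau (log-linear fit), the duration scale of the transient.
    """

    times: np.ndarray
    flux: np.ndarray
    plateau_flux: float
    quasi_steady_flux: float
    settle_time: float
    relaxation_time: float
    relative_difference: float


def transient_cylindrical_wall(
    rest,
    generation: int,
    params: WallTransportParams | None = None,
    c_step: float = 5e-9,
    t_end: float = 1.0,
    nodes_per_layer: int = 80,
) -> TransientWallResult:
    """Transient NO transport in a hollow-cylinder airway wall after a lumen step.

    The epithelium and muscle layers of one airway of the given generation
    (rest geometry, typically constricted) are resolved radially between the
    lumen radius and the outer muscle radius.  Starting from the steady state
    with zero lumen NO, the lumen concentration is stepped to ``c_step`` and
    the full time-dependent axisymmetric diffusion-reaction problem is
    integrated.  The lumen-side flux history is compared with the quasi-steady
    planar-slab law to quantify the curvature and unsteadiness errors.

    Parameters
    ----------
    rest : RestingLungGeometry
        Rest geometry supplying the wall radii (generation <= 18).
    generation : int
        Airway generation to analyse.
    c_step : float
        Lumen NO volume fraction after the step (default 5 ppb).
    """
    from .morphometry import LAST_WALLED_GENERATION

    if not 0 <= generation <= LAST_WALLED_GENERATION:
        raise ValueError("layered walls exist only in generations 0-18")
    p = params if params is not None else WallTransportParams()
    r_in = rest.r_lumen[generation]
    r_mid = rest.r_epithelium[generation]
    r_out = rest.r_muscle[generation]

    n = nodes_per_layer
    r = np.concatenate([np.linspace(r_in, r_mid, n + 1),
                        np.linspace(r_mid, r_out, n + 1)[1:]])
    total = len(r)
    faces = 0.5 * (r[:-1] + r[1:])
    dr = np.diff(r)
    # vertex-centred finite volumes (per radian, unit length)
    vol = np.empty(total)
    vol[0] = 0.5 * (faces[0] ** 2 - r[0] ** 2)
    vol[-1] = 0.5 * (r[-1] ** 2 - faces[-1] ** 2)
    vol[1:-1] = 0.5 * (faces[1:] ** 2 - faces[:-1] ** 2)
    cond = p.d_no_t * faces / dr  # face conductances
    # epithelial production indicator, volume-weighted per cell
    prod = np.zeros(total)
    epi_frac = np.zeros(total)
    epi_frac[: n] = 1.0
    epi_frac[n] = (r_mid**2 - faces[n - 1] ** 2) / (2.0 * vol[n])
    prod = p.pr * epi_frac

    def steady(c_lumen_val: float) -> np.ndarray:
        lo = np.zeros(total)
        di = np.zeros(total)
        hi = np.zeros(total)
        b = np.zeros(total)
        di[0] = 1.0
        b[0] = p.lambda_t_air * c_lumen_val
        di[-1] = 1.0
        b[-1] = 0.0
        for j in range(1, total - 1):
            lo[j] = cond[j - 1] / vol[j]
            hi[j] = cond[j] / vol[j]
            di[j] = -(cond[j - 1] + cond[j]) / vol[j] - p.k
            b[j] = -prod[j]
        ab = np.zeros((3, total))
        ab[0, 1:] = hi[:-1]
        ab[1, :] = di
        ab[2, :-1] = lo[1:]
        from scipy.linalg import solve_banded
        return solve_banded((1, 1), ab, b)

    c0 = steady(0.0)
    c_bc = p.lambda_t_air * c_step

    def rhs(_t, c):
        d = np.zeros_like(c)
        flux_faces = cond * (c[1:] - c[:-1])  # diffusive exchange, inward positive
        d[1:-1] = (flux_faces[1:] - flux_faces[:-1]) / vol[1:-1] \
            + prod[1:-1] - p.k * c[1:-1]
        return d

    def jac(_t, _c):
        band = np.zeros((3, total))
        band[0, 2:] = cond[1:] / vol[1:-1]
        band[2, :-2] = cond[:-1] / vol[1:-1]
        band[1, 1:-1] = -(cond[:-1] + cond[1:]) / vol[1:-1] - p.k
        return band

    y0 = c0.copy()
    y0[0] = c_bc
    t_eval = np.linspace(0.0, t_end, 400)
    sol = solve_ivp(rhs, (0.0, t_end), y0, method="LSODA", jac=jac,
                    lband=1, uband=1, t_eval=t_eval, rtol=1e-8, atol=1e-16)
    if not sol.success:
        raise RuntimeError(f"transient wall integration failed: {sol.message}")
    c = sol.y
    # second-order one-sided gradient at the lumen surface
    h = dr[0]
    dcdr = (-3.0 * c[0] + 4.0 * c[1] - c[2]) / (2.0 * h)
    flux = p.gamma * p.d_no_t * dcdr  # toward the lumen (-r direction)

    plateau = float(flux[-1])
    qs = float(airway_flux_law(
        hatta_numbers(rest.delta_muscle[generation], rest.delta_epithelium[generation],
                      rest.delta_mucus[generation], p), p)(c_step))

    # transient amplitude, excluding the sub-millisecond surface layer that
    # follows the concentration step (mesh-scale, not a wall property)
    dev = np.abs(flux - plateau)
    late = sol.t >= 0.01
    amp = float(dev[late].max(initial=0.0))
    if amp <= max(abs(plateau), 1e-30) * 1e-9:
        settle_time = 0.0
        relaxation_time = 0.0
    else:
        outside = late & (dev > 0.05 * amp)
        idx = int(np.flatnonzero(outside)[-1]) + 1 if outside.any() else 0
        settle_time = float(sol.t[min(idx, len(flux) - 1)])
        # log-linear fit of the decay toward the plateau
        win = late & (dev > 0.01 * amp) & (dev < 0.9 * amp)
        if win.sum() >= 3:
            slope = np.polyfit(sol.t[win], np.log(dev[win]), 1)[0]
            relaxation_time = float(-1.0 / slope) if slope < 0 else float("inf")
        else:
            relaxation_time = settle_time / 3.0
    rel = abs(plateau - qs) / abs(qs) if qs != 0 else (0.0 if plateau == 0 else float("inf"))
    return TransientWallResult(
        times=sol.t,
        flux=flux,
        plateau_flux=plateau,
        quasi_steady_flux=qs,
        settle_time=settle_time,
        relaxation_time=relaxation_time,
        relative_difference=float(rel),
    )
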