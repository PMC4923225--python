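"""Gaseous NO transport in the lumen of the 24-generation airway tree.

Model
-----
Within each generation the cross-sectionally averaged NO volume fraction
``C_i(t, zeta)`` obeys a 1D convection-diffusion-source balance: quasi-steady
convection by the air flow ``Q_i(zeta)``, axial diffusion through the lumen
cross-section ``OmegaPrime_i`` (alveoli store gas but do not transmit it
axially), wall exchange ``J_air`` on the layered airway surface ``S_air,i``
(generations 0-18), and alveolar exchange ``J_alv`` on ``S_alv,i``.  The
cross-sections inflate uniformly during the cycle, which dilutes the gas.

Discretization
--------------
Each generation carries ``n`` equally spaced nodes on ``zeta in [0, 1]``;
the junction between consecutive generations is one shared node, making the
whole tree a single tridiagonally coupled chain.  A vertex-centred finite
volume form is used: upwind convective face fluxes (first-order), centred
diffusive face fluxes (second-order) weighted by the instantaneous flow
cross-section, so the junction condition — equal concentration and equal
total axial diffusive flow — and exact discrete mass conservation hold by
construction.  Boundary conditions: zero NO at the mouth during inspiration,
pure convective exit (zero diffusive flux) during breath-hold and
expiration, zero diffusive flux at the distal end of generation 23.

The semi-discrete system is linear and stiff (fast diffusion in the short
distal generations); it is integrated with LSODA and an analytic banded
Jacobian.  Phases are chained: each phase starts from the final field of the
previous one, and a full-cycle simulation starts from zero NO everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .airflow import DEFAULT_D_NO_AIR, flow_profile
from .cycle import (
    DEFAULT_ALVEOLUS_DIAMETER_CM,
    BreathingPattern,
    Phase,
    wall_radii_at_scale,
)
from .morphometry import LAST_WALLED_GENERATION, N_GENERATIONS, RestingLungGeometry
from .wall import AlveolarParams, WallTransportParams, airway_flux_law, hatta_numbers

PPB = 1e-9

__all__ = ["GridSpec", "ConcentrationField", "PhaseTrajectory", "SimulationResult",
           "TransportModel", "simulate_phase", "simulate_cycle", "mass_balance_audit",
           "PPB"]


@dataclass(frozen=True)
class GridSpec:
    """Spatial grid: ``points_per_generation`` equally spaced zeta-nodes per
    generation, junction nodes shared between neighbours."""

    points_per_generation: int = 20

    def __post_init__(self) -> None:
        if self.points_per_generation < 5:
            raise ValueError("need at least 5 points per generation")

    @property
    def n_nodes(self) -> int:
        return N_GENERATIONS * self.points_per_generation - (N_GENERATIONS - 1)

    @property
    def h(self) -> float:
        return 1.0 / (self.points_per_generation - 1)

    def start_index(self, generation: int) -> int:
        return generation * (self.points_per_generation - 1)

    def zeta(self) -> np.ndarray:
        """Per-node zeta coordinate (junction nodes belong to both sides)."""
        z = np.empty(self.n_nodes)
        for i in range(N_GENERATIONS):
            s = self.start_index(i)
            z[s : s + self.points_per_generation] = np.linspace(0, 1, self.points_per_generation)
        return z

    def generation_of_nodes(self) -> np.ndarray:
        """Owning generation per node (junctions assigned to the distal side)."""
        g = np.empty(self.n_nodes, dtype=int)
        for i in range(N_GENERATIONS):
            s = self.start_index(i)
            g[s : s + self.points_per_generation] = i
        return g

    def node_slice(self, generation: int) -> slice:
        s = self.start_index(generation)
        return slice(s, s + self.points_per_generation)


@dataclass
class ConcentrationField:
    """NO volume fraction on the global node chain at one instant."""

    grid: GridSpec
    values: np.ndarray
    phase: Phase | None = None
    theta: float = 0.0

    def per_generation(self, generation: int) -> np.ndarray:
        return self.values[self.grid.node_slice(generation)]

    @property
    def mouth_ppb(self) -> float:
        return float(self.values[0] / PPB)


@dataclass(frozen=True)
class TransportModel:
    """Physical configuration shared by all phases of one simulation."""

    rest: RestingLungGeometry
    pattern: BreathingPattern
    wall_params: WallTransportParams = field(default_factory=WallTransportParams)
    alveolar: AlveolarParams = field(default_factory=AlveolarParams)
    d_no_air: float = DEFAULT_D_NO_AIR
    d_alv: float = DEFAULT_ALVEOLUS_DIAMETER_CM
    grid: GridSpec = field(default_factory=GridSpec)


class _PhaseOperator:
    """Precomputed arrays and the semi-discrete operator for one phase."""

    def __init__(self, model: TransportModel, phase: Phase):
        self.model = model
        self.phase = phase
        rest, grid = model.rest, model.grid
        n = grid.points_per_generation
        h = grid.h
        m = grid.n_nodes
        self.m = m
        self.dil = model.pattern.dil(rest)
        self.q0 = model.pattern.phase_flow(phase)
        dur = model.pattern.phase_duration(phase)
        self.duration = dur

        # scale factor s(t) and its rate within the phase (dimensional time)
        if phase is Phase.INSPIRATION:
            self.s_of = lambda t: 1.0 + self.dil * t / model.pattern.t_in
            self.sdot = self.dil / model.pattern.t_in
        elif phase is Phase.BREATH_HOLD:
            self.s_of = lambda t: 1.0 + self.dil
            self.sdot = 0.0
        else:
            self.s_of = lambda t: 1.0 + self.dil * (1.0 - t / model.pattern.t_ex)
            self.sdot = -self.dil / model.pattern.t_ex

        gen = grid.generation_of_nodes()
        L = rest.length
        # rest node gas volumes: each node owns half a cell on either side;
        # mouth/terminal nodes own one half cell, junction nodes own a half
        # cell of each neighbouring generation
        w = np.zeros(m)
        for i in range(N_GENERATIONS):
            sl = grid.node_slice(i)
            cell = rest.omega[i] * L[i] * h
            w[sl] += cell
            w[sl.start] -= 0.5 * cell
            w[sl.stop - 1] -= 0.5 * cell
        self.w_rest = w

        # face k couples nodes k and k+1; it is interval j = k mod (n-1) of
        # generation k // (n-1), centred at zeta = (j + 1/2) h
        k = np.arange(m - 1)
        face_gen = k // (n - 1)
        face_zeta = (k % (n - 1) + 0.5) * h
        self.face_gen = face_gen

        flow = flow_profile(rest.volume_fractions, model.pattern, phase)
        self.q_face = flow.flow(face_gen, face_zeta)
        self.q_mouth = float(flow.flow(0, 0.0))
        # rest diffusive conductances D * OmegaPrime / (L h); scale with s(t)
        self.g_rest = model.d_no_air * rest.omega_prime[face_gen] / (L[face_gen] * h)

        # per-node exchange-surface weights (fraction of the generation)
        nw = LAST_WALLED_GENERATION + 1
        self.air_weight = np.zeros(m)   # share of S_air,i(t) per node
        self.air_gen = gen              # generation whose flux law applies
        alv_weight = np.zeros(m)        # share of rest S_alv per node
        s_alv_rest = rest.omega_alv * L * 6.0 / model.d_alv
        for i in range(N_GENERATIONS):
            sl = grid.node_slice(i)
            frac = np.full(n, h)
            frac[0] = frac[-1] = 0.5 * h
            if i <= LAST_WALLED_GENERATION:
                self.air_weight[sl] += frac
            alv_weight[sl] += frac * s_alv_rest[i]
        tot = s_alv_rest.sum()
        self.sigma_alv = alv_weight / tot  # share of total alveolar surface
        self.s_air_rest = np.zeros(N_GENERATIONS)
        self.s_air_rest[:nw] = 2.0 ** np.arange(nw) * 2.0 * np.pi \
            * rest.r_mucus * L[:nw]

        self.dirichlet_mouth = phase is Phase.INSPIRATION
        self._wall_cache: tuple[float, np.ndarray, np.ndarray] | None = None

    # -- wall flux laws at scale s (cached: s varies smoothly within a phase)
    def wall_coeffs(self, s: float) -> tuple[np.ndarray, np.ndarray]:
        if self._wall_cache is not None and abs(self._wall_cache[0] - s) < 1e-13:
            return self._wall_cache[1], self._wall_cache[2]
        rest = self.model.rest
        r_muc, r_lum, r_epi, r_mus = wall_radii_at_scale(rest, s)
        ha = hatta_numbers(r_mus - r_epi, r_epi - r_lum, r_lum - r_muc,
                           self.model.wall_params)
        law = airway_flux_law(ha, self.model.wall_params)
        a = np.asarray(law.a)
        b = np.asarray(law.b)
        self._wall_cache = (s, a, b)
        return a, b

    def _source_coeffs(self, t: float):
        """Linear source ``src = src_a - src_b * C`` per node (ml NO/s)."""
        s = self.s_of(t)
        a_w, b_w = self.wall_coeffs(s)
        s_air = self.s_air_rest * np.sqrt(s)  # S_air,i(t)
        a_gen = np.zeros(N_GENERATIONS)
        b_gen = np.zeros(N_GENERATIONS)
        nw = LAST_WALLED_GENERATION + 1
        a_gen[:nw] = a_w * s_air[:nw]
        b_gen[:nw] = b_w * s_air[:nw]
        src_a = self.air_weight * a_gen[self.air_gen] \
            + self.sigma_alv * self.model.alveolar.p_alv
        src_b = self.air_weight * b_gen[self.air_gen] \
            + self.sigma_alv * self.model.alveolar.u_alv
        return s, src_a, src_b

    def rhs(self, t: float, c: np.ndarray) -> np.ndarray:
        s, src_a, src_b = self._source_coeffs(t)
        w = s * self.w_rest
        g = s * self.g_rest
        up = np.where(self.q_face >= 0, c[:-1], c[1:])
        flux = self.q_face * up - g * np.diff(c)  # positive mouthward->distal
        net = np.zeros(self.m)
        net[:-1] -= flux
        net[1:] += flux
        if not self.dirichlet_mouth:
            net[0] += self.q_mouth * c[0]  # convective exit (q_mouth <= 0)
        d = (net + src_a - src_b * c - c * self.sdot * self.w_rest) / w
        if self.dirichlet_mouth:
            d[0] = 0.0
        return d

    def jac(self, t: float, c: np.ndarray) -> np.ndarray:
        s, _src_a, src_b = self._source_coeffs(t)
        w = s * self.w_rest
        g = s * self.g_rest
        pos = self.q_face >= 0
        p = np.where(pos, self.q_face, 0.0) + g      # d flux_k / d c_k
        q = np.where(pos, 0.0, self.q_face) - g      # d flux_k / d c_{k+1}
        band = np.zeros((3, self.m))
        # diag: -p_k (node k loses via face k) + q_{k-1} (gains via face k-1)
        diag = np.zeros(self.m)
        diag[:-1] -= p
        diag[1:] += q
        if not self.dirichlet_mouth:
            diag[0] += self.q_mouth
        diag -= src_b + self.sdot * self.w_rest
        band[1] = diag / w
        band[0, 1:] = -q / w[:-1]   # upper: d rhs_k / d c_{k+1}
        band[2, :-1] = p / w[1:]    # lower: d rhs_{k+1} / d c_k
        if self.dirichlet_mouth:
            band[1, 0] = 0.0
            band[0, 1] = 0.0
        return band

    def source_totals(self, t: float, c: np.ndarray) -> tuple[float, float]:
        """Instantaneous total wall+alveolar source and mouth outflow (ml NO/s)."""
        _s, src_a, src_b = self._source_coeffs(t)
        source = float(np.sum(src_a - src_b * c))
        if self.dirichlet_mouth:
            outflow = 0.0  # inspired air is NO-free; mouth node held at zero
            s = self.s_of(t)
            g0 = s * self.g_rest[0]
            outflow = -float(g0 * (c[1] - c[0]))  # diffusive loss through mouth
        else:
            outflow = -float(self.q_mouth * c[0])
        return source, outflow


@dataclass
class PhaseTrajectory:
    """Sampled concentration fields over one phase."""

    phase: Phase
    times: np.ndarray  # dimensional time within the phase, s
    fields: np.ndarray  # (n_times, n_nodes)
    operator: _PhaseOperator

    @property
    def final(self) -> np.ndarray:
        return self.fields[-1]


def simulate_phase(
    model: TransportModel,
    phase: Phase,
    initial: np.ndarray,
    n_samples: int = 201,
    rtol: float = 1e-7,
    atol: float = 1e-16,
) -> PhaseTrajectory:
    """Integrate one respiratory phase starting from ``initial`` (volume fraction)."""
    op = _PhaseOperator(model, phase)
    if op.duration <= 0:
        return PhaseTrajectory(phase, np.array([0.0]), initial[None, :].copy(), op)
    y0 = initial.copy()
    if op.dirichlet_mouth:
        y0[0] = 0.0
    t_eval = np.linspace(0.0, op.duration, n_samples)
    sol = solve_ivp(op.rhs, (0.0, op.duration), y0, method="LSODA", jac=op.jac,
                    lband=1, uband=1, t_eval=t_eval, rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(
            f"{phase.value} integration failed: {sol.message}; "
            "try a finer grid or looser tolerances")
    fields = sol.y.T.copy()
    if op.dirichlet_mouth:
        fields[:, 0] = 0.0  # held exactly at the NO-free inspired air
    return PhaseTrajectory(phase, sol.t, fields, op)


@dataclass
class SimulationResult:
    """Chained full-cycle simulation output.

    ``feno_times``/``feno_ppb`` sample the mouth concentration during
    expiration; ``feno_end_ppb`` is the end-expiration value (FE_NO,50 for
    the standard 50 ml/s maneuver).
    """

    model: TransportModel
    phases: list[PhaseTrajectory]
    feno_times: np.ndarray
    feno_ppb: np.ndarray
    feno_end_ppb: float
    mass_residual: float

    @property
    def expiration(self) -> PhaseTrajectory:
        return self.phases[-1]

    def field_at_end(self, phase: Phase) -> ConcentrationField:
        """Concentration field at the end of the last occurrence of ``phase``."""
        for tr in reversed(self.phases):
            if tr.phase is phase:
                return ConcentrationField(self.model.grid, tr.final, phase, 1.0)
        raise KeyError(phase)

    def feno_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.feno_times, "feno_ppb": self.feno_ppb})

    def concentration_frame(self) -> pd.DataFrame:
        """Tidy per-node concentrations at the end of each phase (ppb)."""
        grid = self.model.grid
        gen = grid.generation_of_nodes()
        zeta = grid.zeta()
        frames = []
        for tr in self.phases:
            frames.append(pd.DataFrame({
                "phase": tr.phase.value,
                "generation": gen,
                "zeta": zeta,
                "C_ppb": tr.final / PPB,
            }))
        return pd.concat(frames, ignore_index=True)


def simulate_cycle(
    model: TransportModel,
    n_samples: int = 201,
    rtol: float = 1e-7,
    n_cycles: int = 1,
) -> SimulationResult:
    """Simulate ``n_cycles`` chained respiratory cycles from NO-free lungs.

    The default single cycle starting from zero NO is the FE_NO measurement
    protocol.  ``n_cycles > 1`` chains identical cycles (each phase starting
    from the previous end state) to reach the cyclic regime of ongoing
    breathing, in which the distal generations hold their 2-3 ppb plateau
    throughout; reported FE_NO series come from the last expiration.
    """
    grid = model.grid
    c = np.zeros(grid.n_nodes)
    phases: list[PhaseTrajectory] = []
    for _ in range(n_cycles):
        for phase in (Phase.INSPIRATION, Phase.BREATH_HOLD, Phase.EXPIRATION):
            if model.pattern.phase_duration(phase) <= 0:
                continue
            tr = simulate_phase(model, phase, c, n_samples=n_samples, rtol=rtol)
            phases.append(tr)
            c = tr.final
    exp = phases[-1]
    feno = exp.fields[:, 0] / PPB
    residual = mass_balance_audit(phases)
    return SimulationResult(
        model=model,
        phases=phases,
        feno_times=exp.times,
        feno_ppb=feno,
        feno_end_ppb=float(feno[-1]),
        mass_residual=residual,
    )


def mass_balance_audit(phases: list[PhaseTrajectory]) -> float:
    """Relative NO mass-balance defect of a simulated trajectory.

    Compares the change of the total gaseous NO inventory with the
    time-integrated wall/alveolar sources minus the mouth outflow, using the
    sampled fields and trapezoidal quadrature; the result is normalised by
    the integrated production.  The spatial scheme is conservative, so the
    defect measures time-sampling error only.
    """
    produced = 0.0
    defect = 0.0
    for tr in phases:
        op = tr.operator
        n_t = len(tr.times)
        if n_t < 2:
            continue
        rates = np.array([op.source_totals(t, c) for t, c in zip(tr.times, tr.fields)])
        net_rate = rates[:, 0] - rates[:, 1]
        gained = np.trapezoid(net_rate, tr.times)
        produced += np.trapezoid(np.abs(rates[:, 0]), tr.times)
        w0 = op.s_of(tr.times[0]) * op.w_rest
        w1 = op.s_of(tr.times[-1]) * op.w_rest
        stored = float(np.sum(w1 * tr.fields[-1]) - np.sum(w0 * tr.fields[0]))
        defect += stored - gained
    return abs(defect) / produced if produced > 0 else abs(defect)
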