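"""Desk-scale unsteady hydrodynamics of one or two undulating swimmers.

The solver is a 2-D unsteady discrete-vortex (lumped-vortex) panel method
on the horizontal midplane of the body: the deforming midline is divided
into flat panels carrying point vortices at their quarter-chord points,
no-penetration is enforced at three-quarter-chord collocation points, a
point vortex is shed from the trailing edge each step (its strength fixed
jointly by the collocation system and Kelvin's circulation theorem, which
realizes the Kutta condition), and the free wake is advected with the
local velocity.  Surface pressure differences follow from the unsteady
Bernoulli equation; skin friction is modelled per panel with the turbulent
flat-plate correlation acting on the local tangential velocity — the body
undulates at a Reynolds number of order 10⁵, where the boundary layer is
transitional-to-turbulent.

This is intentionally inviscid-plus-correction physics: it captures the
wake-interference mechanisms of pair swimming (phase and separation
effects, Bénard–von Kármán-type wake organization) at interactive cost,
not the absolute force levels of a 3-D viscous computation.

Conventions: the flow frame holds the fish stationary with inlet flow in
``+x`` (the fish swims toward ``−x``); ``y`` is lateral.  Point-vortex
circulation is positive counterclockwise.  Thrust is the ``−x`` force
component, drag the ``+x`` component.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Literal

import numpy as np
import yaml

from fishwake.geometry import (
    FishGeometry,
    lateral_displacement_m,
    lateral_velocity_m,
)
from fishwake.kinematics import BodyWaveParams, envelope

__all__ = [
    "FluidProperties",
    "Swimmer",
    "SimConfig",
    "WakeState",
    "SimulationResult",
    "SolverBlowUpError",
    "simulate",
    "friction_drag_coefficient",
    "reynolds_number",
    "strouhal_number",
    "balance_frequency",
    "sample_flow",
    "FlowSample",
]

#: Pair separations (model lengths) used in the replication sweeps.
REPLICATION_SEPARATIONS = (0.4, 0.6, 0.8, 1.2, 1.6, 2.0)


class SolverBlowUpError(RuntimeError):
    """Wake-induced velocities exceeded the stability guard."""


@dataclass(frozen=True)
class FluidProperties:
    """Water at tank conditions; temperature is metadata only."""

    density: float = 998.0  # kg/m^3
    viscosity: float = 1.02e-3  # Pa s
    temperature: float = 20.0  # degC

    def __post_init__(self) -> None:
        if self.density <= 0 or self.viscosity <= 0:
            raise ValueError("density and viscosity must be positive")


@dataclass(frozen=True)
class Swimmer:
    """One undulating body: geometry, kinematics, placement and wave phase."""

    geometry: FishGeometry
    params: BodyWaveParams
    y_offset: float = 0.0  # lateral placement of the undeformed midline, m
    phase: float = 0.0  # additive phase of the body wave, rad


@dataclass(frozen=True)
class SimConfig:
    """Configuration of a solitary or pair run.

    ``speed_bl_s`` is the inlet speed in body lengths per second;
    ``separation_L`` the lateral gap between the two midlines in model
    lengths (pair runs only); ``phase_relation`` selects tail-beat
    synchrony (``inphase``) or opposition (``antiphase``).  Discretization:
    ``n_panels`` midline panels per body, ``steps_per_period`` timesteps
    per tail-beat period, ``n_periods`` simulated periods of which the
    first ``transient_periods`` are discarded from averages, and a wake
    truncation cap ``wake_cap_L`` model lengths behind the trailing edge.
    """

    speed_bl_s: float
    swimmers: tuple[Swimmer, ...]
    separation_L: float | None = None
    phase_relation: Literal["inphase", "antiphase"] = "inphase"
    n_panels: int = 40
    steps_per_period: int = 100
    n_periods: int = 8
    transient_periods: int = 2
    wake_cap_L: float = 6.0
    vortex_core_L: float = 0.02

    def __post_init__(self) -> None:
        if self.speed_bl_s <= 0:
            raise ValueError("inlet speed must be positive")
        if len(self.swimmers) not in (1, 2):
            raise ValueError("1 or 2 swimmers are supported")
        if self.n_panels < 4:
            raise ValueError("n_panels must be >= 4")
        if self.n_periods <= self.transient_periods:
            raise ValueError("n_periods must exceed transient_periods")
        if len(self.swimmers) == 2:
            gap = abs(self.swimmers[0].y_offset - self.swimmers[1].y_offset)
            if gap <= 0:
                raise ValueError("pair runs require non-overlapping placement")

    @classmethod
    def solitary(
        cls,
        speed_bl_s: float,
        params: BodyWaveParams,
        geometry: FishGeometry | None = None,
        **kwargs,
    ) -> "SimConfig":
        geometry = geometry or FishGeometry()
        return cls(
            speed_bl_s=speed_bl_s,
            swimmers=(Swimmer(geometry, params),),
            **kwargs,
        )

    @classmethod
    def pair(
        cls,
        speed_bl_s: float,
        params: BodyWaveParams,
        separation_L: float,
        phase_relation: Literal["inphase", "antiphase"] = "inphase",
        geometry: FishGeometry | None = None,
        **kwargs,
    ) -> "SimConfig":
        """Two identical swimmers, midlines ``separation_L`` model lengths apart.

        The pair straddles ``y = 0``; antiphase gives the second body a π
        wave-phase offset (its motion is the mirror image of the first).
        """
        if separation_L <= 0:
            raise ValueError("separation must be positive")
        geometry = geometry or FishGeometry()
        half = 0.5 * separation_L * geometry.length
        phi = math.pi if phase_relation == "antiphase" else 0.0
        swimmers = (
            Swimmer(geometry, params, y_offset=+half, phase=0.0),
            Swimmer(geometry, params, y_offset=-half, phase=phi),
        )
        return cls(
            speed_bl_s=speed_bl_s,
            swimmers=swimmers,
            separation_L=separation_L,
            phase_relation=phase_relation,
            **kwargs,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        raw = yaml.safe_load(Path(path).read_text())
        params = BodyWaveParams.from_dict(raw["params"])
        geom_kwargs = raw.get("geometry", {})
        geometry = FishGeometry(**geom_kwargs)
        disc = {
            k: raw[k]
            for k in (
                "n_panels",
                "steps_per_period",
                "n_periods",
                "transient_periods",
                "wake_cap_L",
                "vortex_core_L",
            )
            if k in raw
        }
        if raw.get("separation_L") is not None:
            return cls.pair(
                speed_bl_s=float(raw["speed_bl_s"]),
                params=params,
                separation_L=float(raw["separation_L"]),
                phase_relation=raw.get("phase_relation", "inphase"),
                geometry=geometry,
                **disc,
            )
        return cls.solitary(
            speed_bl_s=float(raw["speed_bl_s"]),
            params=params,
            geometry=geometry,
            **disc,
        )

    def with_frequency(self, frequency: float) -> "SimConfig":
        """Same run with every swimmer's tail-beat frequency replaced."""
        swimmers = tuple(
            replace(s, params=replace(s.params, frequency=frequency))
            for s in self.swimmers
        )
        return replace(self, swimmers=swimmers)

    @property
    def period(self) -> float:
        return self.swimmers[0].params.period

    @property
    def dt(self) -> float:
        return self.period / self.steps_per_period

    @property
    def inlet_speed_m_s(self) -> float:
        return self.speed_bl_s * self.swimmers[0].geometry.body_length


@dataclass
class WakeState:
    """Free point-vortex wake plus per-body circulation bookkeeping."""

    positions: np.ndarray  # (n, 2) m
    circulations: np.ndarray  # (n,) m^2/s, counterclockwise positive
    ages: np.ndarray  # (n,) s
    body_index: np.ndarray  # (n,) which body shed each vortex
    truncated_circulation: np.ndarray  # (n_bodies,) removed by the wake cap

    @classmethod
    def empty(cls, n_bodies: int) -> "WakeState":
        return cls(
            positions=np.zeros((0, 2)),
            circulations=np.zeros(0),
            ages=np.zeros(0),
            body_index=np.zeros(0, dtype=int),
            truncated_circulation=np.zeros(n_bodies),
        )


@dataclass
class SimulationResult:
    """Per-timestep surface forces, wake history and flow-sampling state.

    Array shapes use ``S`` timesteps, ``B`` bodies and ``N`` panels per
    body.  Pressure and friction forces are full 3-D-equivalent newtons
    (2-D strip force × body height).  ``transient_steps`` marks the first
    index retained for averaging.
    """

    config: SimConfig
    fluid: FluidProperties
    times: np.ndarray  # (S,)
    panel_midpoints: np.ndarray  # (S, B, N, 2) m
    panel_pressure: np.ndarray  # (S, B, N) Pa (pressure difference)
    pressure_force: np.ndarray  # (S, B, N, 2) N
    friction_force: np.ndarray  # (S, B, N, 2) N
    panel_velocity: np.ndarray  # (S, B, N, 2) m/s prescribed element motion
    bound_positions: np.ndarray  # (S, B, N, 2) m
    bound_circulations: np.ndarray  # (S, B, N) m^2/s
    wake_history: list[WakeState]
    transient_steps: int
    kelvin_drift: np.ndarray  # (S,) |Σ bound + Σ wake + Σ truncated|
    max_shed_circulation: float
    vortex_core: float

    @property
    def n_bodies(self) -> int:
        return len(self.config.swimmers)

    @property
    def steady_slice(self) -> slice:
        return slice(self.transient_steps, None)

    def total_force(self, body: int) -> np.ndarray:
        """(S, 2) total pressure + friction force history of one body."""
        return self.pressure_force[:, body].sum(axis=1) + self.friction_force[
            :, body
        ].sum(axis=1)

    def mean_thrust_drag(self, body: int | None = None) -> tuple[float, float]:
        """Post-transient time-averaged (F_T, F_D) in newtons.

        Thrust is the summed −x pressure components of thrust-directed
        elements; drag the +x pressure components plus friction, per the
        surface-force definitions used throughout.
        """
        sl = self.steady_slice
        fx_p = self.pressure_force[sl][..., 0]  # (S', B, N)
        fx_f = self.friction_force[sl][..., 0]
        if body is not None:
            fx_p = fx_p[:, body : body + 1]
            fx_f = fx_f[:, body : body + 1]
        thrust = np.clip(-fx_p, 0.0, None).sum(axis=(1, 2))
        drag = np.clip(fx_p, 0.0, None).sum(axis=(1, 2)) + fx_f.sum(axis=(1, 2))
        return float(thrust.mean()), float(drag.mean())

    def forces_to_csv(self, path: str | Path) -> None:
        import pandas as pd

        rows = {"t_s": self.times}
        for b in range(self.n_bodies):
            fx_p = self.pressure_force[:, b, :, 0]
            fx_f = self.friction_force[:, b, :, 0]
            rows[f"F_T_body{b}_N"] = np.clip(-fx_p, 0.0, None).sum(axis=1)
            rows[f"F_D_body{b}_N"] = (
                np.clip(fx_p, 0.0, None).sum(axis=1) + fx_f.sum(axis=1)
            )
            rows[f"F_lat_body{b}_N"] = (
                self.pressure_force[:, b, :, 1].sum(axis=1)
                + self.friction_force[:, b, :, 1].sum(axis=1)
            )
        pd.DataFrame(rows).to_csv(path, index=False)

    def wake_to_csv(self, path: str | Path) -> None:
        import pandas as pd

        frames = []
        for t, wk in zip(self.times, self.wake_history):
            if len(wk.circulations) == 0:
                continue
            frames.append(
                pd.DataFrame(
                    {
                        "t_s": t,
                        "x_m": wk.positions[:, 0],
                        "y_m": wk.positions[:, 1],
                        "circulation_m2_s": wk.circulations,
                        "body": wk.body_index,
                    }
                )
            )
        import pandas as pd  # noqa: F811

        pd.concat(frames, ignore_index=True).to_csv(path, index=False)


@dataclass(frozen=True)
class FlowSample:
    """Velocity samples at field points; ``inside_body`` rows are NaN."""

    points: np.ndarray  # (M, 2) m
    velocities: np.ndarray  # (M, 2) m/s
    inside_body: np.ndarray  # (M,) bool


# ---------------------------------------------------------------------------
# Dimensionless numbers and the friction model


def reynolds_number(
    speed_bl_s: float,
    geometry: FishGeometry | None = None,
    fluid: FluidProperties | None = None,
) -> float:
    """Body Reynolds number ρ·(U·BL)·L/μ.

    The swimming speed is given in body lengths per second and converted
    on the body-length scale; the characteristic length is the total model
    length.
    """
    geometry = geometry or FishGeometry()
    fluid = fluid or FluidProperties()
    u = speed_bl_s * geometry.body_length
    return fluid.density * u * geometry.length / fluid.viscosity


def strouhal_number(
    params: BodyWaveParams, speed_bl_s: float, x_tip_bl: float = 1.13
) -> float:
    """Strouhal number St = f·A/U with A the peak-to-peak tail excursion.

    ``A = 2·envelope(x_tip)`` in BL and ``U`` in BL/s, so the body-length
    scale cancels.  Both the amplitude definition (peak-to-peak) and the
    tail-tip station are explicit because reported St values are sensitive
    to them.
    """
    if speed_bl_s <= 0:
        raise ValueError("speed must be positive")
    amplitude = 2.0 * envelope(x_tip_bl, params)
    return params.frequency * amplitude / speed_bl_s


def friction_drag_coefficient(reynolds: float) -> float:
    """Turbulent flat-plate friction coefficient C_f = 0.074 · Re^{−1/5}."""
    if reynolds <= 0:
        raise ValueError("Reynolds number must be positive")
    return 0.074 * reynolds ** (-0.2)


# ---------------------------------------------------------------------------
# Vortex kernels


def _induced_velocity(
    targets: np.ndarray,
    sources: np.ndarray,
    circulations: np.ndarray,
    core: float,
) -> np.ndarray:
    """Velocity at ``targets`` induced by point vortices at ``sources``.

    A Lamb–Oseen-type core of radius ``core`` regularizes the kernel
    (``core = 0`` gives the singular kernel).  Counterclockwise-positive
    circulation.
    """
    if len(sources) == 0:
        return np.zeros_like(targets)
    dx = targets[:, 0:1] - sources[None, :, 0]
    dy = targets[:, 1:2] - sources[None, :, 1]
    r2 = dx * dx + dy * dy
    r2 = np.maximum(r2, 1e-24)
    factor = circulations[None, :] / (2.0 * np.pi * r2)
    if core > 0:
        factor = factor * (1.0 - np.exp(-r2 / (core * core)))
    return np.column_stack(
        [(-dy * factor).sum(axis=1), (dx * factor).sum(axis=1)]
    )


def _unit_influence(targets: np.ndarray, sources: np.ndarray, core: float):
    """(M, K) u and v influence matrices of unit vortices."""
    dx = targets[:, 0:1] - sources[None, :, 0]
    dy = targets[:, 1:2] - sources[None, :, 1]
    r2 = np.maximum(dx * dx + dy * dy, 1e-24)
    factor = 1.0 / (2.0 * np.pi * r2)
    if core > 0:
        factor = factor * (1.0 - np.exp(-r2 / (core * core)))
    return -dy * factor, dx * factor


# ---------------------------------------------------------------------------
# Panel bookkeeping


def _panel_endpoints_x(
    geom: FishGeometry, n_panels: int, spacing: str = "cosine"
) -> np.ndarray:
    if spacing == "uniform":
        return np.linspace(0.0, 1.0, n_panels + 1) * geom.length
    return 0.5 * (1.0 - np.cos(np.linspace(0.0, np.pi, n_panels + 1))) * geom.length


@dataclass
class _BodyPanels:
    """Instantaneous panel geometry and motion of one deforming midline."""

    endpoints: np.ndarray  # (N+1, 2)
    vortex_points: np.ndarray  # (N, 2) quarter-chord
    collocation: np.ndarray  # (N, 2) three-quarter-chord
    tangents: np.ndarray  # (N, 2) unit, snout → tail
    normals: np.ndarray  # (N, 2) unit, +y side
    lengths: np.ndarray  # (N,)
    velocity: np.ndarray  # (N, 2) prescribed motion at collocation points
    shed_point: np.ndarray  # (2,) new wake vortex position


def _build_panels(
    swimmer: Swimmer,
    x_end: np.ndarray,
    t: float,
    phase_params: BodyWaveParams,
    shed_offset: float,
) -> _BodyPanels:
    geom = swimmer.geometry
    y_end = swimmer.y_offset + lateral_displacement_m(
        x_end, t, phase_params, geom
    )
    endpoints = np.column_stack([x_end, y_end])
    delta = np.diff(endpoints, axis=0)
    lengths = np.linalg.norm(delta, axis=1)
    tangents = delta / lengths[:, None]
    normals = np.column_stack([-tangents[:, 1], tangents[:, 0]])
    vortex_points = endpoints[:-1] + 0.25 * delta
    collocation = endpoints[:-1] + 0.75 * delta
    x_cp = collocation[:, 0]
    vy = lateral_velocity_m(x_cp, t, phase_params, geom)
    velocity = np.column_stack([np.zeros_like(vy), vy])
    shed_point = endpoints[-1] + shed_offset * tangents[-1]
    return _BodyPanels(
        endpoints=endpoints,
        vortex_points=vortex_points,
        collocation=collocation,
        tangents=tangents,
        normals=normals,
        lengths=lengths,
        velocity=velocity,
        shed_point=shed_point,
    )


def _swimmer_time(swimmer: Swimmer, t: float) -> float:
    # additive phase φ is equivalent to a time shift φ/(2πf)
    return t + swimmer.phase / (2.0 * np.pi * swimmer.params.frequency)


# ---------------------------------------------------------------------------
# Main time-stepping loop


def simulate(
    config: SimConfig, fluid: FluidProperties | None = None
) -> SimulationResult:
    """Run the unsteady discrete-vortex simulation.

    Each step deforms the bodies to time ``t``, solves the no-penetration
    system jointly for all bound vortices and one newly shed trailing-edge
    vortex per body (Kelvin's theorem supplies the per-body closure, which
    enforces the Kutta condition), evaluates unsteady-Bernoulli pressure
    differences and flat-plate friction on every panel, and advects the
    free wake.  The first ``transient_periods`` periods are flagged as
    impulsive-start transient; averages exclude them.

    Raises
    ------
    SolverBlowUpError
        If any wake-induced speed exceeds 50× the inlet speed.
    numpy.linalg.LinAlgError
        If the panel system is singular (degenerate geometry).
    """
    fluid = fluid or FluidProperties()
    n_bodies = len(config.swimmers)
    n_panels = config.n_panels
    u_inf = np.array([config.inlet_speed_m_s, 0.0])
    speed = config.inlet_speed_m_s
    dt = config.dt
    n_steps = config.n_periods * config.steps_per_period

    x_ends = [
        _panel_endpoints_x(s.geometry, n_panels) for s in config.swimmers
    ]
    # Lamb-core radius is a fixed physical fraction of the model length so
    # that the wake dynamics are independent of the surface discretization
    # (a core tied to panel size would change the physics under refinement)
    core = config.vortex_core_L * max(
        s.geometry.length for s in config.swimmers
    )
    # shed spacing follows the free-stream travel per step so the nascent
    # vortex sits where the wake sheet it discretizes would be
    shed_offset = 0.25 * config.inlet_speed_m_s * dt
    re = reynolds_number(config.speed_bl_s, config.swimmers[0].geometry, fluid)
    cf = friction_drag_coefficient(re)

    wake = WakeState.empty(n_bodies)
    phi_prev = [np.zeros(n_panels) for _ in range(n_bodies)]

    times = np.zeros(n_steps)
    panel_midpoints = np.zeros((n_steps, n_bodies, n_panels, 2))
    panel_pressure = np.zeros((n_steps, n_bodies, n_panels))
    pressure_force = np.zeros((n_steps, n_bodies, n_panels, 2))
    friction_force = np.zeros((n_steps, n_bodies, n_panels, 2))
    panel_velocity = np.zeros((n_steps, n_bodies, n_panels, 2))
    bound_positions = np.zeros((n_steps, n_bodies, n_panels, 2))
    bound_circulations = np.zeros((n_steps, n_bodies, n_panels))
    wake_history: list[WakeState] = []
    kelvin_drift = np.zeros(n_steps)
    max_shed = 0.0

    n_unknowns = n_bodies * (n_panels + 1)
    height = config.swimmers[0].geometry.height
    tail_x = max(x[-1] for x in x_ends)
    cap_x = tail_x + config.wake_cap_L * config.swimmers[0].geometry.length

    for step in range(n_steps):
        t = (step + 1) * dt
        times[step] = t
        panels = [
            _build_panels(
                s, x_ends[b], _swimmer_time(s, t), s.params, shed_offset
            )
            for b, s in enumerate(config.swimmers)
        ]

        cps = np.vstack([p.collocation for p in panels])
        nrm = np.vstack([p.normals for p in panels])
        body_vel = np.vstack([p.velocity for p in panels])

        # assemble influence matrix: bound vortices (singular kernel) and one
        # nascent shed vortex per body (regularized like the wake)
        a_mat = np.zeros((n_unknowns, n_unknowns))
        col = 0
        src_all = []
        for b, p in enumerate(panels):
            u_m, v_m = _unit_influence(cps, p.vortex_points, core=0.0)
            a_mat[: len(cps), col : col + n_panels] = (
                u_m * nrm[:, 0:1] + v_m * nrm[:, 1:2]
            )
            col += n_panels
            u_s, v_s = _unit_influence(cps, p.shed_point[None, :], core=core)
            a_mat[: len(cps), col : col + 1] = (
                u_s * nrm[:, 0:1] + v_s * nrm[:, 1:2]
            )
            col += 1
            src_all.append(p.vortex_points)

        # Kelvin closure per body: Σ bound + new shed = −(old wake + truncated)
        rhs = np.zeros(n_unknowns)
        for b in range(n_bodies):
            row = len(cps) + b
            start = b * (n_panels + 1)
            a_mat[row, start : start + n_panels + 1] = 1.0
            old = wake.circulations[wake.body_index == b].sum()
            rhs[row] = -(old + wake.truncated_circulation[b])

        wake_at_cp = _induced_velocity(
            cps, wake.positions, wake.circulations, core
        )
        free = u_inf[None, :] + wake_at_cp
        rhs[: len(cps)] = -np.einsum("ij,ij->i", free - body_vel, nrm)

        sol = np.linalg.solve(a_mat, rhs)

        gammas = []
        new_vortices = []
        for b, p in enumerate(panels):
            start = b * (n_panels + 1)
            g = sol[start : start + n_panels]
            shed = sol[start + n_panels]
            gammas.append(g)
            new_vortices.append((p.shed_point, shed, b))
            max_shed = max(max_shed, abs(shed))

        # --- surface loads ------------------------------------------------
        for b, p in enumerate(panels):
            ext = u_inf[None, :] + _induced_velocity(
                p.collocation, wake.positions, wake.circulations, core
            )
            for bb, pp in enumerate(panels):
                if bb != b:
                    ext = ext + _induced_velocity(
                        p.collocation, pp.vortex_points, gammas[bb], 0.0
                    )
            for pos, g, _ in new_vortices:
                ext = ext + _induced_velocity(
                    p.collocation, pos[None, :], np.array([g]), core
                )
            rel = ext - p.velocity
            v_t = np.einsum("ij,ij->i", rel, p.tangents)
            phi = np.cumsum(gammas[b])
            dphi_dt = (phi - phi_prev[b]) / dt
            phi_prev[b] = phi
            # unsteady Bernoulli pressure difference across the sheet
            dp = fluid.density * (v_t * gammas[b] / p.lengths + dphi_dt)
            f_press = -(
                fluid.density
                * (v_t * gammas[b] + p.lengths * dphi_dt)[:, None]
                * p.normals
            ) * height
            v_t_vec = v_t[:, None] * p.tangents
            speed_t = np.abs(v_t)
            f_fric = (
                0.5
                * fluid.density
                * cf
                * speed_t[:, None]
                * v_t_vec
                * (2.0 * p.lengths[:, None])
            ) * height

            panel_midpoints[step, b] = 0.5 * (p.endpoints[:-1] + p.endpoints[1:])
            panel_pressure[step, b] = dp
            pressure_force[step, b] = f_press
            friction_force[step, b] = f_fric
            panel_velocity[step, b] = p.velocity
            bound_positions[step, b] = p.vortex_points
            bound_circulations[step, b] = gammas[b]

        # --- wake update --------------------------------------------------
        all_bound_pos = np.vstack([p.vortex_points for p in panels])
        all_bound_gam = np.concatenate(gammas)
        if len(wake.positions):
            w_vel = (
                u_inf[None, :]
                + _induced_velocity(
                    wake.positions, wake.positions, wake.circulations, core
                )
                + _induced_velocity(
                    wake.positions, all_bound_pos, all_bound_gam, core
                )
            )
            for pos, g, _ in new_vortices:
                w_vel = w_vel + _induced_velocity(
                    wake.positions, pos[None, :], np.array([g]), core
                )
            induced_speed = np.linalg.norm(w_vel - u_inf[None, :], axis=1)
            if induced_speed.size and induced_speed.max() > 50.0 * speed:
                raise SolverBlowUpError(
                    f"induced wake speed {induced_speed.max():.3g} m/s exceeds "
                    f"50× inlet speed at t={t:.4f} s (step {step})"
                )
            new_pos = wake.positions + dt * w_vel
        else:
            new_pos = wake.positions

        positions = np.vstack([new_pos] + [p[None, :] for p, _, _ in new_vortices])
        circulations = np.concatenate(
            [wake.circulations, [g for _, g, _ in new_vortices]]
        )
        ages = np.concatenate([wake.ages + dt, np.zeros(n_bodies)])
        body_index = np.concatenate(
            [wake.body_index, [b for _, _, b in new_vortices]]
        ).astype(int)
        truncated = wake.truncated_circulation.copy()
        keep = positions[:, 0] <= cap_x
        if not np.all(keep):
            for b in range(n_bodies):
                truncated[b] += circulations[(~keep) & (body_index == b)].sum()
        wake = WakeState(
            positions=positions[keep],
            circulations=circulations[keep],
            ages=ages[keep],
            body_index=body_index[keep],
            truncated_circulation=truncated,
        )
        wake_history.append(wake)

        total = (
            all_bound_gam.sum()
            + wake.circulations.sum()
            + wake.truncated_circulation.sum()
        )
        kelvin_drift[step] = abs(total)

    return SimulationResult(
        config=config,
        fluid=fluid,
        times=times,
        panel_midpoints=panel_midpoints,
        panel_pressure=panel_pressure,
        pressure_force=pressure_force,
        friction_force=friction_force,
        panel_velocity=panel_velocity,
        bound_positions=bound_positions,
        bound_circulations=bound_circulations,
        wake_history=wake_history,
        transient_steps=config.transient_periods * config.steps_per_period,
        kelvin_drift=kelvin_drift,
        max_shed_circulation=max_shed,
        vortex_core=core,
    )


# ---------------------------------------------------------------------------
# Self-propulsion balance


def balance_frequency(
    config: SimConfig,
    fluid: FluidProperties | None = None,
    bracket: tuple[float, float] = (1.0, 4.0),
    tolerance: float = 0.05,
    max_iter: int = 40,
) -> float:
    """Tail-beat frequency at which time-averaged thrust balances drag.

    Bisects on frequency until ``|F_T/F_D − 1| ≤ tolerance`` with all other
    parameters fixed; mean thrust grows with frequency while drag is
    dominated by friction, so the imbalance is monotone over a sensible
    bracket.

    Raises
    ------
    ValueError
        If the imbalance does not change sign over ``bracket`` (the
        endpoint thrust/drag ratios are reported).
    """
    fluid = fluid or FluidProperties()

    def imbalance(freq: float) -> tuple[float, float]:
        result = simulate(config.with_frequency(freq), fluid)
        ft, fd = result.mean_thrust_drag()
        return ft - fd, ft / fd

    lo, hi = bracket
    g_lo, r_lo = imbalance(lo)
    if abs(r_lo - 1.0) <= tolerance:
        return lo
    g_hi, r_hi = imbalance(hi)
    if abs(r_hi - 1.0) <= tolerance:
        return hi
    if g_lo * g_hi > 0:
        raise ValueError(
            "thrust−drag imbalance does not change sign over the bracket: "
            f"F_T/F_D = {r_lo:.3f} at {lo} Hz and {r_hi:.3f} at {hi} Hz"
        )
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        g_mid, r_mid = imbalance(mid)
        if abs(r_mid - 1.0) <= tolerance:
            return mid
        if g_lo * g_mid <= 0:
            hi = mid
        else:
            lo, g_lo = mid, g_mid
    raise RuntimeError(
        f"balance_frequency did not converge in {max_iter} bisections"
    )


# ---------------------------------------------------------------------------
# Flow sampling


def sample_flow(
    result: SimulationResult, points: np.ndarray, t: float
) -> FlowSample:
    """Velocity at arbitrary field points at a simulated instant.

    The velocity is free stream plus the regularized induction of every
    bound panel vortex and wake vortex at the timestep nearest ``t``.
    Points inside a body section (within the local NACA half-thickness of
    the deformed midline) are flagged and their velocity set to NaN rather
    than raising.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    times = result.times
    if t < times[0] - 1e-12 or t > times[-1] + 1e-12:
        raise ValueError(
            f"t={t} outside the simulated window [{times[0]}, {times[-1]}]"
        )
    step = int(np.argmin(np.abs(times - t)))
    t_step = times[step]
    u_inf = np.array([result.config.inlet_speed_m_s, 0.0])
    core = result.vortex_core
    wake = result.wake_history[step]
    vel = u_inf[None, :] + _induced_velocity(
        points, wake.positions, wake.circulations, core
    )
    for b in range(result.n_bodies):
        vel = vel + _induced_velocity(
            points,
            result.bound_positions[step, b],
            result.bound_circulations[step, b],
            core,
        )

    from fishwake.geometry import naca_half_thickness

    inside = np.zeros(len(points), dtype=bool)
    for b, swimmer in enumerate(result.config.swimmers):
        geom = swimmer.geometry
        x = points[:, 0]
        in_chord = (x >= 0.0) & (x <= geom.length)
        if not np.any(in_chord):
            continue
        xc = np.clip(x[in_chord] / geom.length, 0.0, 1.0)
        half = naca_half_thickness(xc, geom.thickness_ratio) * geom.length
        y_mid = swimmer.y_offset + lateral_displacement_m(
            x[in_chord], _swimmer_time(swimmer, t_step), swimmer.params, geom
        )
        inside[in_chord] |= np.abs(points[in_chord, 1] - y_mid) <= half
    vel[inside] = np.nan
    return FlowSample(points=points, velocities=vel, inside_body=inside)
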