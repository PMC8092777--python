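r"""Force decomposition, Froude efficiency, wake transects and pair sweeps.

Forces on the body surface are decomposed in the swimming frame: thrust is
the ``−x`` (swimming-direction) component of the pressure force on
thrust-directed elements, drag the ``+x`` pressure component plus skin
friction.  The Froude efficiency

.. math:: \eta = \frac{P_T}{P_T + P_S},

compares useful thrust power ``P_T = ⟨Σ_i F_{Ti} u_i⟩`` against the power
``P_S = ⟨Σ_i F_{Si} v_i⟩`` spent driving the lateral recoil, where ``u_i``
is the element's travel-direction speed (the swimming speed — the
prescribed wave has no axial component) and ``v_i`` its lateral velocity.
``F_{Si}`` is the lateral force the element exerts on the fluid, so
``P_S ≥ 0`` for a driven oscillation and ``η ∈ [0, 1]``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from fishwake.hydro import (
    FluidProperties,
    SimConfig,
    SimulationResult,
    balance_frequency,
    sample_flow,
    simulate,
)

__all__ = [
    "ElementForceHistory",
    "ForceTimeSeries",
    "EfficiencyResult",
    "WakeTransect",
    "decompose_forces",
    "thrust_drag_series",
    "froude_efficiency",
    "wake_transect",
    "solitary_transect",
    "parallel_sweep",
]


@dataclass(frozen=True)
class ElementForceHistory:
    """Per-element force decomposition over the retained time window.

    Arrays are shaped ``(S, B, N)`` (timestep, body, element).  The
    decomposition is exact: ``−thrust + drag_pressure`` recovers the axial
    pressure force and ``−lateral`` the lateral pressure force on the body.

    Attributes
    ----------
    thrust :
        ``F_Ti`` — thrust-direction (−x) pressure-force components of
        thrust-directed elements, N (zero on drag-directed elements).
    drag_pressure :
        +x pressure-force components of drag-directed elements, N.
    friction_x, friction_y :
        Skin-friction force components on the body, N.
    lateral :
        ``F_Si`` — lateral force exerted by the element on the fluid, N.
    axial_velocity :
        ``u_i`` — element speed along the direction of travel, m/s
        (the swimming speed; the prescribed wave is purely lateral).
    lateral_velocity :
        ``v_i`` — prescribed element lateral velocity, m/s.
    """

    times: np.ndarray
    thrust: np.ndarray
    drag_pressure: np.ndarray
    friction_x: np.ndarray
    friction_y: np.ndarray
    lateral: np.ndarray
    axial_velocity: np.ndarray
    lateral_velocity: np.ndarray
    period: float
    dt: float
    n_bodies: int


@dataclass(frozen=True)
class ForceTimeSeries:
    """Instantaneous and period-averaged thrust/drag of a run."""

    times: np.ndarray
    thrust: np.ndarray  # (S,) N
    drag: np.ndarray  # (S,) N
    mean_thrust: float
    mean_drag: float
    ratio: float

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"t_s": self.times, "F_T_N": self.thrust, "F_D_N": self.drag}
        ).to_csv(path, index=False)


@dataclass(frozen=True)
class EfficiencyResult:
    """Froude efficiency and its power components.

    ``eta`` pools both bodies of a pair run; ``per_body`` carries the
    per-body (η, P_T, P_S) triples.
    """

    eta: float
    thrust_power: float  # P_T, W
    lateral_power: float  # P_S, W
    per_body: tuple[tuple[float, float, float], ...]
    separation_L: float | None = None
    phase_relation: str | None = None
    speed_bl_s: float | None = None
    frequency_hz: float | None = None


@dataclass(frozen=True)
class WakeTransect:
    """Time-averaged apparent flow speed along a downstream sampling line."""

    distances_L: np.ndarray
    speed_bl_s: np.ndarray
    speed_ratio: np.ndarray  # relative to the inlet speed
    origin: tuple[float, float]

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "distance_L": self.distances_L,
                "speed_bl_s": self.speed_bl_s,
                "speed_ratio": self.speed_ratio,
            }
        ).to_csv(path, index=False)


def _integer_period_slice(result: SimulationResult) -> slice:
    """Longest post-transient window spanning whole tail-beat periods."""
    spp = result.config.steps_per_period
    total = len(result.times) - result.transient_steps
    n_periods = total // spp
    if n_periods < 1:
        raise ValueError("fewer than one full period after the transient")
    start = len(result.times) - n_periods * spp
    return slice(start, None)


def decompose_forces(result: SimulationResult) -> ElementForceHistory:
    """Split per-element surface forces into thrust/drag/lateral components.

    Operates on the post-transient window truncated to whole periods.  The
    axial pressure force of each element goes to thrust (−x part) or drag
    (+x part); friction is kept separate and charged to drag in
    :func:`thrust_drag_series`; the lateral component is reported as the
    force on the fluid (sign-flipped pressure force) so that lateral power
    is positive for a driven oscillation.
    """
    sl = _integer_period_slice(result)
    fp = result.pressure_force[sl]
    ff = result.friction_force[sl]
    fx = fp[..., 0]
    u = result.config.inlet_speed_m_s
    return ElementForceHistory(
        times=result.times[sl],
        thrust=np.clip(-fx, 0.0, None),
        drag_pressure=np.clip(fx, 0.0, None),
        friction_x=ff[..., 0],
        friction_y=ff[..., 1],
        lateral=-fp[..., 1],
        axial_velocity=np.full_like(fx, u),
        lateral_velocity=result.panel_velocity[sl][..., 1],
        period=result.config.period,
        dt=result.config.dt,
        n_bodies=result.n_bodies,
    )


def thrust_drag_series(forces: ElementForceHistory) -> ForceTimeSeries:
    """Instantaneous and period-averaged total thrust and drag."""
    thrust = forces.thrust.sum(axis=(1, 2))
    drag = forces.drag_pressure.sum(axis=(1, 2)) + forces.friction_x.sum(
        axis=(1, 2)
    )
    mean_t = float(thrust.mean())
    mean_d = float(drag.mean())
    return ForceTimeSeries(
        times=forces.times,
        thrust=thrust,
        drag=drag,
        mean_thrust=mean_t,
        mean_drag=mean_d,
        ratio=mean_t / mean_d if mean_d != 0 else math.inf,
    )


def _body_powers(forces: ElementForceHistory, body: int) -> tuple[float, float]:
    pt = float(
        (forces.thrust[:, body] * forces.axial_velocity[:, body])
        .sum(axis=1)
        .mean()
    )
    ps = float(
        (forces.lateral[:, body] * forces.lateral_velocity[:, body])
        .sum(axis=1)
        .mean()
    )
    return pt, ps


def froude_efficiency(
    forces: ElementForceHistory,
    separation_L: float | None = None,
    phase_relation: str | None = None,
    speed_bl_s: float | None = None,
    frequency_hz: float | None = None,
) -> EfficiencyResult:
    """Froude efficiency η = P_T/(P_T + P_S) over the averaging window.

    Raises
    ------
    ValueError
        If the pooled ``P_T + P_S`` is nonpositive (unphysical window).
    """
    per_body = []
    pt_total = ps_total = 0.0
    for b in range(forces.n_bodies):
        pt, ps = _body_powers(forces, b)
        denom = pt + ps
        eta_b = pt / denom if denom > 0 else math.nan
        per_body.append((eta_b, pt, ps))
        pt_total += pt
        ps_total += ps
    if pt_total + ps_total <= 0:
        raise ValueError(
            f"total power P_T + P_S = {pt_total + ps_total:.3g} W is not "
            "positive; the averaging window is unphysical"
        )
    return EfficiencyResult(
        eta=pt_total / (pt_total + ps_total),
        thrust_power=pt_total,
        lateral_power=ps_total,
        per_body=tuple(per_body),
        separation_L=separation_L,
        phase_relation=phase_relation,
        speed_bl_s=speed_bl_s,
        frequency_hz=frequency_hz,
    )


def _transect(
    result: SimulationResult,
    origin: tuple[float, float],
    range_L: tuple[float, float],
    n_samples: int,
    n_periods_avg: int = 2,
) -> WakeTransect:
    model_length = result.config.swimmers[0].geometry.length
    distances = np.linspace(range_L[0], range_L[1], n_samples)
    points = np.column_stack(
        [origin[0] + distances * model_length, np.full(n_samples, origin[1])]
    )
    spp = result.config.steps_per_period
    n_avg = min(n_periods_avg * spp, len(result.times) - result.transient_steps)
    steps = range(len(result.times) - n_avg, len(result.times))
    speeds = np.zeros(n_samples)
    for s in steps:
        sample = sample_flow(result, points, result.times[s])
        speeds += np.linalg.norm(sample.velocities, axis=1)
    speeds /= len(list(steps))
    bl = result.config.swimmers[0].geometry.body_length
    return WakeTransect(
        distances_L=distances,
        speed_bl_s=speeds / bl,
        speed_ratio=speeds / result.config.inlet_speed_m_s,
        origin=origin,
    )


def wake_transect(
    result: SimulationResult,
    range_L: tuple[float, float] = (0.5, 2.0),
    n_samples: int = 40,
    n_periods_avg: int = 2,
) -> WakeTransect:
    """Apparent flow speed along the mid-line behind a swimming pair.

    Samples the time-averaged velocity magnitude on the line parallel to
    the flow through the midpoint of the two snouts, over the final
    ``n_periods_avg`` tail-beat periods, and reports it in BL/s and as a
    ratio to the inlet speed.

    Raises
    ------
    ValueError
        For single-body results; use :func:`solitary_transect` instead.
    """
    if result.n_bodies != 2:
        raise ValueError(
            "wake_transect requires a two-body simulation; use "
            "solitary_transect for a single swimmer"
        )
    s0, s1 = result.config.swimmers
    origin = (0.0, 0.5 * (s0.y_offset + s1.y_offset))
    return _transect(result, origin, range_L, n_samples, n_periods_avg)


def solitary_transect(
    result: SimulationResult,
    range_L: tuple[float, float] = (0.5, 2.0),
    n_samples: int = 40,
    n_periods_avg: int = 2,
) -> WakeTransect:
    """Apparent flow speed along the body axis behind a single swimmer."""
    if result.n_bodies != 1:
        raise ValueError("solitary_transect requires a single-body simulation")
    origin = (0.0, result.config.swimmers[0].y_offset)
    return _transect(result, origin, range_L, n_samples, n_periods_avg)


def _efficiency_of(result: SimulationResult, **echo) -> EfficiencyResult:
    return froude_efficiency(decompose_forces(result), **echo)


def parallel_sweep(
    base: SimConfig,
    separations: tuple[float, ...] = (0.4, 0.6, 0.8, 1.2, 1.6, 2.0),
    phases: tuple[str, ...] = ("inphase", "antiphase"),
    fluid: FluidProperties | None = None,
    rebalance: bool = True,
    bracket: tuple[float, float] = (0.8, 3.5),
    balance_tolerance: float = 0.05,
    include_solitary: bool = True,
) -> pd.DataFrame:
    """Efficiency table over the separation × phase grid plus a solitary row.

    For every (separation, phase) cell a pair run is configured from
    ``base`` (which supplies speed, kinematics and discretization); the
    tail-beat frequency is rebalanced to the self-propelled state when
    ``rebalance`` is set, the run simulated and the Froude efficiency
    computed.  Failures are recorded in the ``error`` column and the sweep
    continues.  The returned frame has one row per cell plus the solitary
    reference (``phase = "solitary"``).
    """
    fluid = fluid or FluidProperties()
    params = base.swimmers[0].params
    geometry = base.swimmers[0].geometry
    disc = dict(
        n_panels=base.n_panels,
        steps_per_period=base.steps_per_period,
        n_periods=base.n_periods,
        transient_periods=base.transient_periods,
        wake_cap_L=base.wake_cap_L,
        vortex_core_L=base.vortex_core_L,
    )

    def run_cell(config: SimConfig, sep, phase) -> dict:
        row = {
            "separation_L": sep,
            "phase": phase,
            "f_balanced_hz": config.swimmers[0].params.frequency,
        }
        try:
            if rebalance:
                f_star = balance_frequency(
                    config, fluid, bracket=bracket, tolerance=balance_tolerance
                )
                config = config.with_frequency(f_star)
                row["f_balanced_hz"] = f_star
            result = simulate(config, fluid)
            forces = decompose_forces(result)
            series = thrust_drag_series(forces)
            eff = froude_efficiency(forces)
            row.update(
                F_T_N=series.mean_thrust,
                F_D_N=series.mean_drag,
                P_T_W=eff.thrust_power,
                P_S_W=eff.lateral_power,
                eta=eff.eta,
                error="",
            )
        except Exception as exc:  # per-cell failure; sweep continues
            row.update(
                F_T_N=math.nan,
                F_D_N=math.nan,
                P_T_W=math.nan,
                P_S_W=math.nan,
                eta=math.nan,
                error=f"{type(exc).__name__}: {exc}",
            )
        return row

    rows = []
    if include_solitary:
        rows.append(
            run_cell(
                SimConfig.solitary(base.speed_bl_s, params, geometry, **disc),
                None,
                "solitary",
            )
        )
    for sep in separations:
        for phase in phases:
            config = SimConfig.pair(
                base.speed_bl_s,
                params,
                separation_L=sep,
                phase_relation=phase,  # type: ignore[arg-type]
                geometry=geometry,
                **disc,
            )
            rows.append(run_cell(config, sep, phase))
    return pd.DataFrame(rows)
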