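"""Quasi-static time stepping of the cargo-drag force balance.

At every step the centrosome velocity is the algebraic root of the
force-balance equation (inertia is negligible at low Reynolds number):

    6 pi R_v sum_i n_i (v_vm c_i - u)  =  r (6 pi R_c + sum_i zeta_i) u

with n_i = rho L_i the vesicle count on rod i, c_i its axis cosine, zeta_i
its slender-body drag coefficient and r the aster-to-vesicle viscosity
ratio.  The position is then advanced by explicit Euler and the rods grow at
the polymerization rate, clamped so no rod tip ever crosses the cell wall.
A wall-clamped rod resumes growing if the advancing centrosome opens up room
toward that side; rods never depolymerize.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np

from .errors import ModelError
from .hydrodynamics import (
    PARALLEL_LOG_CONSTANT,
    PERPENDICULAR_LOG_CONSTANT,
    DragBreakdown,
    sphere_drag_coefficient,
    vesicle_axis_force_terms,
    slender_body_coefficient,
)
from .model_core import (
    AxisFrame,
    EmbryoGeometry,
    MicrotubuleArray,
    ModelParams,
    generate_aster,
    make_geometry,
    max_length_to_cortex,
)

__all__ = ["Trajectory", "solve_velocity", "grow_microtubules", "run"]

logger = logging.getLogger(__name__)

#: slack (µm) below the wall distance at which a rod counts as touching
_CONTACT_TOL = 1e-9


@dataclass
class Trajectory:
    """Time series of the centring run.

    times : (N+1,) sample times (s), uniform step dt
    centrosome_coords : signed distance to the centre along x_hat (µm)
    centrosome_speeds : quasi-static centrosome speed at each sample
        (µm/s, positive toward the centre)
    far_touch_time / near_touch_time : first time a rod tip touches the wall
        on the far or near cortical side, or None if it never does.  Sides
        are the hemispheres cut by the plane through the cell centre normal
        to the centring axis: a contact counts as "far" when the touching
        tip lies beyond that plane (axis coordinate of the tip > 0).
    drag_breakdowns : optional per-sample force-balance decomposition
    """

    times: np.ndarray
    centrosome_coords: np.ndarray
    centrosome_speeds: np.ndarray
    far_touch_time: float | None = None
    near_touch_time: float | None = None
    drag_breakdowns: list[DragBreakdown] | None = None

    def __len__(self) -> int:
        return len(self.times)

    @property
    def displacements(self) -> np.ndarray:
        """Displacement toward the centre since t=0 (µm)."""
        return self.centrosome_coords[0] - self.centrosome_coords


def _force_balance_terms(
    lengths: np.ndarray,
    axis_cosines: np.ndarray,
    params: ModelParams,
    geometry: EmbryoGeometry,
) -> tuple[float, float, float, float]:
    """(pull_sum, back_reaction, centrosome_coeff, mt_coeff_sum) of the balance."""
    stokes_v = sphere_drag_coefficient(params.vesicle_radius)
    counts = params.vesicle_density * lengths
    pull_sum = stokes_v * params.vesicle_speed * float(counts @ axis_cosines)
    back_reaction = stokes_v * float(counts.sum())
    centro = sphere_drag_coefficient(geometry.centrosome_radius)
    zeta = slender_body_coefficient(lengths, params.mt_radius, axis_cosines)
    return pull_sum, back_reaction, centro, float(np.sum(zeta))


def solve_velocity(
    mts: MicrotubuleArray, geometry: EmbryoGeometry, params: ModelParams
) -> float:
    """Centrosome speed u (µm/s, positive toward the centre) from the balance.

    Closed form: u = pull_sum / (back_reaction + r (6 pi R_c + sum zeta_i)).
    The denominator is strictly positive for positive radii, so the root is
    unique.  Depends on the viscosities only through their ratio r.
    """
    if len(mts) == 0:
        raise ModelError("cannot solve the force balance for an empty microtubule array")
    pull, back, centro, zeta_sum = _force_balance_terms(
        mts.lengths, mts.axis_cosines, params, geometry
    )
    return pull / (back + params.viscosity_ratio * (centro + zeta_sum))


def grow_microtubules(
    mts: MicrotubuleArray,
    frame: AxisFrame,
    geometry: EmbryoGeometry,
    params: ModelParams,
) -> MicrotubuleArray:
    """One polymerization step with cortex clamping; returns a new array.

    Each length advances by ``polymerization_rate * time_step`` but is capped
    at the current centrosome-to-wall distance along its direction.  The cap
    is re-evaluated at the current centrosome position, so a rod clamped at
    the near wall regains growing room once the centrosome has moved away.
    """
    limits = max_length_to_cortex(frame, geometry, mts.directions)
    limits = np.asarray(limits, dtype=float).reshape(-1)
    grown = np.minimum(mts.lengths + params.polymerization_rate * params.time_step, limits)
    at_boundary = grown >= limits - _CONTACT_TOL
    return MicrotubuleArray(
        directions=mts.directions,
        lengths=grown,
        axis_cosines=mts.axis_cosines,
        at_boundary=at_boundary,
    )


def run(
    params: ModelParams,
    geometry: EmbryoGeometry | None = None,
    seed: int | None = None,
    record_drag: bool = False,
) -> Trajectory:
    """Simulate one centring run and return its trajectory.

    The loop over ``ceil(duration / dt)`` steps is: solve the force balance
    for the centrosome speed, advance the signed coordinate by explicit
    Euler (``s <- s - u dt``), then grow the rods with the cortex clamp at
    the new position.  The sample at index k is the state at time k*dt, so a
    run with ``duration = 0`` is the single initial point.  Fully
    deterministic given ``(params, geometry, seed)``.

    The centrosome coordinate is clamped to ``|s| <= cell_radius -
    centrosome_radius`` as a safety guard (logged if it ever triggers; it
    should not for realistic parameters).
    """
    if geometry is None:
        geometry = EmbryoGeometry(500.0, 2.0, 4.0)
    _, frame = make_geometry(
        geometry.cell_radius, geometry.centrosome_radius, geometry.initial_wall_distance
    )
    mts = generate_aster(params, frame, seed)

    dt = params.time_step
    n_steps = math.ceil(params.duration / dt)
    R = geometry.cell_radius
    s_max = R - geometry.centrosome_radius
    r = params.viscosity_ratio
    rate_dt = params.polymerization_rate * dt
    stokes_v = sphere_drag_coefficient(params.vesicle_radius)
    centro = sphere_drag_coefficient(geometry.centrosome_radius)
    rho = params.vesicle_density
    v_vm = params.vesicle_speed
    a = params.mt_radius

    c = mts.axis_cosines.copy()
    c2 = c * c
    L = mts.lengths.copy()
    s = frame.centrosome_coord

    # clamp seed lengths in case the wall is closer than mt_initial_length
    disc = np.sqrt(c2 * s * s + R * R - s * s)
    L = np.minimum(L, s * c + disc)

    times = np.arange(n_steps + 1) * dt
    coords = np.empty(n_steps + 1)
    speeds = np.empty(n_steps + 1)
    breakdowns: list[DragBreakdown] | None = [] if record_drag else None
    far_touch: float | None = None
    near_touch: float | None = None

    for k in range(n_steps + 1):
        log_term = np.log(2.0 * L / a)
        zeta_sum = float(
            np.sum(
                2.0 * np.pi * L * c2 / (log_term + PARALLEL_LOG_CONSTANT)
                + 4.0 * np.pi * L * (1.0 - c2) / (log_term + PERPENDICULAR_LOG_CONSTANT)
            )
        )
        pull = stokes_v * v_vm * rho * float(L @ c)
        back = stokes_v * rho * float(L.sum())
        u = pull / (back + r * (centro + zeta_sum))
        coords[k] = s
        speeds[k] = u
        if record_drag:
            breakdowns.append(
                DragBreakdown(
                    vesicle_pull_coefficient=stokes_v * rho * abs(float(L @ c)),
                    vesicle_back_reaction=back,
                    centrosome_coefficient=centro,
                    mt_coefficient_sum=zeta_sum,
                )
            )
        if k == n_steps:
            break

        s_new = s - u * dt
        if abs(s_new) > s_max:
            logger.warning(
                "centrosome clamped at the cell wall (|s|=%.3f µm > %.3f µm)",
                abs(s_new),
                s_max,
            )
            s_new = math.copysign(s_max, s_new)
        s = s_new

        # grow with the cortex clamp at the new position
        disc = np.sqrt(c2 * s * s + R * R - s * s)
        limits = s * c + disc
        L = np.minimum(L + rate_dt, limits)
        touched = L >= limits - _CONTACT_TOL
        if far_touch is None or near_touch is None:
            # tip axis coordinate: -s + L c (> 0 on the far hemisphere)
            tip_on_far_side = (L * c - s) > 0.0
            t_next = float(times[k + 1])
            if far_touch is None and bool(np.any(touched & tip_on_far_side)):
                far_touch = t_next
            if near_touch is None and bool(np.any(touched & ~tip_on_far_side)):
                near_touch = t_next

    return Trajectory(
        times=times,
        centrosome_coords=coords,
        centrosome_speeds=speeds,
        far_touch_time=far_touch,
        near_touch_time=near_touch,
        drag_breakdowns=breakdowns,
    )
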