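"""Domain types, coordinate conventions and the seeded random aster generator.

Geometry convention
-------------------
The embryo is a sphere of radius ``cell_radius`` centred at the origin.  The
centrosome (carrying the male pronucleus) starts a few micrometres from the
cell wall and is only allowed to move along the axis joining its initial
position to the cell centre.  We call the unit vector of that axis ``x_hat``
(pointing *toward* the centre) and track the centrosome by its signed
coordinate ``s``: the distance remaining to the centre, positive on the
starting side and decreasing toward zero as the centrosome centres.  The
centrosome position vector is therefore ``-s * x_hat``.

Microtubules are straight rigid rods nucleated at the centrosome with fixed,
isotropically random directions ``e_i`` (unit vectors from the centrosome
toward the plus end, fixed in the lab frame); they co-translate rigidly with
the centrosome.  The cosine ``c_i = e_i . x_hat`` of the angle between rod
*i* and the direction of motion enters both the slender-body drag and the
projection of the vesicle pulling force on the axis.

All lengths are in µm, times in s, speeds in µm/s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError, ParameterError

__all__ = [
    "EmbryoGeometry",
    "ModelParams",
    "MicrotubuleArray",
    "AxisFrame",
    "make_geometry",
    "generate_aster",
    "max_length_to_cortex",
    "baseline_geometry",
    "baseline_params",
]

#: unit-vector normalisation tolerance for MicrotubuleArray invariants
_UNIT_TOL = 1e-9


@dataclass(frozen=True)
class EmbryoGeometry:
    """Spherical embryo with an embedded centrosome sphere.

    Parameters
    ----------
    cell_radius
        Radius of the spherical cell boundary (µm).
    centrosome_radius
        Radius ``R_c`` of the sphere representing the centrosome together
        with the attached male pronucleus (µm).
    initial_wall_distance
        Distance from the initial centrosome position to the nearest point
        of the cell wall (µm).
    """

    cell_radius: float
    centrosome_radius: float
    initial_wall_distance: float

    def __post_init__(self) -> None:
        if not self.cell_radius > self.centrosome_radius > 0:
            raise ParameterError(
                "require cell_radius > centrosome_radius > 0, got "
                f"cell_radius={self.cell_radius}, centrosome_radius={self.centrosome_radius}"
            )
        if not 0 < self.initial_wall_distance < self.cell_radius:
            raise ParameterError(
                "initial_wall_distance must lie in (0, cell_radius), got "
                f"initial_wall_distance={self.initial_wall_distance}"
            )


@dataclass(frozen=True)
class ModelParams:
    """Physical constants of the cargo-drag force balance.

    Defaults are the baseline embryo conditions: 100 nm diameter vesicles
    hauled at 2 µm/s toward the centrosome, 2 vesicles per µm of microtubule,
    an aster of 100 microtubules growing at 250 nm/s from 2 µm seeds, and an
    aster-to-vesicle effective viscosity ratio of 3.  Only the viscosity
    *ratio* ``r = eta_c / eta_v`` enters the dynamics; absolute viscosities
    never appear.

    Attributes
    ----------
    vesicle_radius
        Cargo radius ``R_v`` (µm).
    vesicle_speed
        Speed ``v_vm`` of a cargo relative to its microtubule (µm/s),
        directed toward the minus end (the centrosome).  Zero is allowed as
        a degenerate no-transport control.
    vesicle_density
        Linear density ``rho`` of motor-hauled cargoes on each microtubule
        (vesicles/µm); counts are treated as continuous averages.
    viscosity_ratio
        ``r = eta_c / eta_v``, effective viscosity felt by the aster
        (centrosome + microtubules) over that felt by the vesicles.
    polymerization_rate
        Microtubule growth speed (µm/s).
    mt_count
        Number of microtubules in the aster.
    mt_initial_length
        Seed length of every microtubule (µm).
    mt_radius
        Microtubule cross-section radius ``a`` (µm); enters only through
        the slender-body logarithm.
    time_step
        Explicit-Euler step ``dt`` (s).
    duration
        Total simulated time (s).
    seed
        Default RNG seed for the aster generator.
    aster_dimension
        2 (default) draws microtubule directions isotropically in the
        equatorial plane containing the centring axis — the plane the
        embryo simulation lives in; 3 draws them isotropically on the full
        unit sphere.  The planar aster reproduces the observed embryo
        dynamics (velocity ramp, 45-minute displacement); the spherical one
        is retained for sensitivity checks.
    """

    vesicle_radius: float = 0.05
    vesicle_speed: float = 2.0
    vesicle_density: float = 2.0
    viscosity_ratio: float = 3.0
    polymerization_rate: float = 0.25
    mt_count: int = 100
    mt_initial_length: float = 2.0
    mt_radius: float = 0.0125
    time_step: float = 0.5
    duration: float = 2700.0
    seed: int = 0
    aster_dimension: int = 2

    def __post_init__(self) -> None:
        positive = (
            "vesicle_radius",
            "vesicle_density",
            "viscosity_ratio",
            "polymerization_rate",
            "mt_initial_length",
            "mt_radius",
            "time_step",
        )
        for name in positive:
            value = getattr(self, name)
            if not value > 0:
                raise ParameterError(f"{name} must be strictly positive, got {value}")
        if self.vesicle_speed < 0:
            raise ParameterError(
                f"vesicle_speed must be nonnegative, got {self.vesicle_speed}"
            )
        if self.duration < 0:
            raise ParameterError(f"duration must be nonnegative, got {self.duration}")
        if int(self.mt_count) != self.mt_count or self.mt_count < 1:
            raise ParameterError(f"mt_count must be an integer >= 1, got {self.mt_count}")
        if self.aster_dimension not in (2, 3):
            raise ParameterError(
                f"aster_dimension must be 2 or 3, got {self.aster_dimension}"
            )
        # slender-body log terms must be positive at the seed length
        if not self.mt_initial_length > self.mt_radius * math.exp(0.5) / 2.0:
            raise ParameterError(
                "mt_initial_length must exceed mt_radius*exp(0.5)/2 so the "
                "slender-body logarithms stay positive, got "
                f"mt_initial_length={self.mt_initial_length}, mt_radius={self.mt_radius}"
            )


@dataclass(frozen=True)
class AxisFrame:
    """Lab frame anchored at the cell centre with the centring axis x_hat.

    ``centrosome_coord`` is the signed distance remaining to the centre
    along ``axis_unit`` (µm): positive on the starting side, decreasing to
    zero as the centrosome centres.  Positive centrosome velocity means
    motion toward the centre.
    """

    origin: np.ndarray
    axis_unit: np.ndarray
    centrosome_coord: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))
        object.__setattr__(self, "axis_unit", np.asarray(self.axis_unit, dtype=float))
        if abs(np.linalg.norm(self.axis_unit) - 1.0) > _UNIT_TOL:
            raise GeometryError("axis_unit must be a unit vector")

    def centrosome_position(self) -> np.ndarray:
        """Centrosome position vector in the lab frame."""
        return self.origin - self.centrosome_coord * self.axis_unit


@dataclass
class MicrotubuleArray:
    """Directions, lengths and boundary-contact state of the aster rods.

    directions : (N, 3) array of unit vectors e_i (centrosome -> plus end)
    lengths : (N,) array of current rod lengths L_i (µm)
    axis_cosines : (N,) array of c_i = e_i . x_hat
    at_boundary : (N,) boolean array, True where the rod tip touches the wall
    """

    directions: np.ndarray
    lengths: np.ndarray
    axis_cosines: np.ndarray
    at_boundary: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.directions = np.atleast_2d(np.asarray(self.directions, dtype=float))
        self.lengths = np.atleast_1d(np.asarray(self.lengths, dtype=float))
        self.axis_cosines = np.atleast_1d(np.asarray(self.axis_cosines, dtype=float))
        if self.at_boundary is None:
            self.at_boundary = np.zeros(len(self.lengths), dtype=bool)
        else:
            self.at_boundary = np.atleast_1d(np.asarray(self.at_boundary, dtype=bool))
        norms = np.linalg.norm(self.directions, axis=1)
        if np.any(np.abs(norms - 1.0) > _UNIT_TOL):
            raise GeometryError("all microtubule directions must be unit vectors")
        if np.any(np.abs(self.axis_cosines) > 1.0 + _UNIT_TOL):
            raise GeometryError("axis cosines must lie in [-1, 1]")

    def __len__(self) -> int:
        return len(self.lengths)


def make_geometry(
    cell_radius: float, centrosome_radius: float, wall_distance: float
) -> tuple[EmbryoGeometry, AxisFrame]:
    """Build the embryo geometry and the centring-axis frame.

    The axis unit vector points from the initial centrosome position toward
    the cell centre, and the initial signed coordinate is
    ``cell_radius - wall_distance``.
    """
    geometry = EmbryoGeometry(cell_radius, centrosome_radius, wall_distance)
    frame = AxisFrame(
        origin=np.zeros(3),
        axis_unit=np.array([1.0, 0.0, 0.0]),
        centrosome_coord=cell_radius - wall_distance,
    )
    return geometry, frame


def baseline_geometry() -> EmbryoGeometry:
    """The 1000 µm diameter embryo with a 2 µm centrosome starting 4 µm from the wall."""
    return EmbryoGeometry(cell_radius=500.0, centrosome_radius=2.0, initial_wall_distance=4.0)


def baseline_params(**overrides) -> ModelParams:
    """Baseline transport parameters; keyword overrides replace single fields."""
    return ModelParams(**overrides)


def generate_aster(
    params: ModelParams, frame: AxisFrame, seed: int | None = None
) -> MicrotubuleArray:
    """Draw ``mt_count`` isotropic microtubule directions from a seeded RNG.

    Sampling is exact (no rejection).  With ``aster_dimension = 2`` the rods
    are isotropic in the equatorial plane containing the centring axis: the
    angle to ``x_hat`` is uniform on [0, 2pi), so the axis cosines follow
    the arcsine law.  With ``aster_dimension = 3`` the cosine of the polar
    angle measured from ``x_hat`` is uniform on [-1, 1] and the azimuth is
    uniform on [0, 2pi) (uniform on the unit sphere).  All rods start at
    ``mt_initial_length``.  The same ``(params, seed)`` pair always
    reproduces the same array bit-for-bit.
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    n = int(params.mt_count)

    # orthonormal basis (x_hat, u, v) completing the centring axis
    x_hat = frame.axis_unit
    helper = np.array([0.0, 1.0, 0.0]) if abs(x_hat[0]) > 0.9 else np.array([1.0, 0.0, 0.0])
    u = np.cross(x_hat, helper)
    u /= np.linalg.norm(u)
    v = np.cross(x_hat, u)

    if params.aster_dimension == 2:
        theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
        cos_theta = np.cos(theta)
        sin_theta = np.sin(theta)
        directions = (
            cos_theta[:, None] * x_hat[None, :] + sin_theta[:, None] * u[None, :]
        )
    else:
        cos_theta = rng.uniform(-1.0, 1.0, size=n)
        phi = rng.uniform(0.0, 2.0 * np.pi, size=n)
        sin_theta = np.sqrt(np.clip(1.0 - cos_theta**2, 0.0, None))
        directions = (
            cos_theta[:, None] * x_hat[None, :]
            + (sin_theta * np.cos(phi))[:, None] * u[None, :]
            + (sin_theta * np.sin(phi))[:, None] * v[None, :]
        )
    lengths = np.full(n, params.mt_initial_length)
    return MicrotubuleArray(
        directions=directions,
        lengths=lengths,
        axis_cosines=cos_theta,
        at_boundary=np.zeros(n, dtype=bool),
    )


def max_length_to_cortex(
    frame: AxisFrame, geometry: EmbryoGeometry, direction: np.ndarray
) -> float | np.ndarray:
    """Distance from the centrosome to the cell wall along ``direction``.

    Solves |p + L e| = cell_radius for the positive root, with p the
    centrosome position.  With the centrosome at signed coordinate ``s`` and
    ``c = e . x_hat`` this is ``L* = s c + sqrt(s^2 c^2 + R^2 - s^2)``.

    Accepts a single direction (shape (3,)) or a stack (N, 3); returns a
    scalar or an (N,) array accordingly.
    """
    s = frame.centrosome_coord
    R = geometry.cell_radius
    if abs(s) >= R:
        raise GeometryError(
            f"centrosome coordinate {s} µm is not strictly inside the cell (radius {R} µm)"
        )
    direction = np.asarray(direction, dtype=float)
    single = direction.ndim == 1
    c = np.atleast_2d(direction) @ frame.axis_unit
    L = s * c + np.sqrt(s * s * c * c + R * R - s * s)
    return float(L[0]) if single else L
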