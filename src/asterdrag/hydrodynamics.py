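"""Low-Reynolds drag coefficients and the vesicle pulling-force terms.

Every coefficient here is a *mobility-free* drag coefficient: force per unit
speed with the viscosity factored out, so it carries units of length (µm).
Multiplying by the relevant effective viscosity (eta_v for vesicles, eta_c
for the centrosome and microtubules) restores the physical drag; since the
force balance divides one side by the other, only the ratio
``r = eta_c / eta_v`` survives.

The aster rods use classical slender-body theory for a translating straight
cylinder of length L and radius a:

    zeta_par  = 2 pi L / (ln(2L/a) - 1/2)     (motion along the rod axis)
    zeta_perp = 4 pi L / (ln(2L/a) + 1/2)     (motion normal to the axis)

and the drag of a rod inclined at angle alpha to the direction of motion is

    zeta(L, a, alpha) = zeta_par cos^2(alpha) + zeta_perp sin^2(alpha).

The additive constants in the logarithms (-1/2, +1/2) are exposed as keyword
arguments so their (logarithmically weak) influence can be probed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .model_core import MicrotubuleArray, ModelParams

__all__ = [
    "DragBreakdown",
    "sphere_drag_coefficient",
    "slender_body_coefficient",
    "vesicle_axis_force_terms",
]

#: additive constants of the slender-body logarithms (translating rod)
PARALLEL_LOG_CONSTANT = -0.5
PERPENDICULAR_LOG_CONSTANT = 0.5


@dataclass(frozen=True)
class DragBreakdown:
    """Decomposition of the force balance at one instant.

    All entries are drag coefficients (µm): ``vesicle_pull_coefficient`` is
    the motor pulling term divided by the cargo speed relative to the
    microtubule, ``vesicle_back_reaction`` the coefficient multiplying the
    centrosome speed in the vesicle term; both are normalized by eta_v.
    ``centrosome_coefficient`` and ``mt_coefficient_sum`` are normalized by
    eta_c.
    """

    vesicle_pull_coefficient: float
    vesicle_back_reaction: float
    centrosome_coefficient: float
    mt_coefficient_sum: float

    def __post_init__(self) -> None:
        for name in (
            "vesicle_pull_coefficient",
            "vesicle_back_reaction",
            "centrosome_coefficient",
            "mt_coefficient_sum",
        ):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be nonnegative")


def sphere_drag_coefficient(radius: float) -> float:
    """Stokes drag coefficient 6*pi*R of a sphere, viscosity factored out (µm)."""
    if not radius > 0:
        raise ParameterError(f"radius must be strictly positive, got {radius}")
    return 6.0 * math.pi * radius


def slender_body_coefficient(
    length,
    mt_radius: float,
    axis_cosine,
    parallel_log_constant: float = PARALLEL_LOG_CONSTANT,
    perpendicular_log_constant: float = PERPENDICULAR_LOG_CONSTANT,
):
    """Slender-body drag coefficient of an inclined rigid rod (µm).

    Parameters
    ----------
    length, mt_radius
        Rod length L and cross-section radius a (µm); requires
        ln(2L/a) + parallel_log_constant > 0.
    axis_cosine
        cos(alpha) of the angle between the rod and the direction of motion.

    Accepts scalars or broadcastable arrays.
    """
    if not mt_radius > 0:
        raise ParameterError(f"mt_radius must be strictly positive, got {mt_radius}")
    L = np.asarray(length, dtype=float)
    c = np.asarray(axis_cosine, dtype=float)
    if np.any(L <= 0):
        raise ParameterError("rod length must be strictly positive")
    if np.any(np.abs(c) > 1.0 + 1e-12):
        raise ParameterError("axis_cosine must lie in [-1, 1]")
    log_term = np.log(2.0 * L / mt_radius)
    denom_par = log_term + parallel_log_constant
    denom_perp = log_term + perpendicular_log_constant
    if np.any(denom_par <= 0) or np.any(denom_perp <= 0):
        raise ParameterError(
            "degenerate rod: slender-body logarithm nonpositive (rod too short "
            "relative to its radius)"
        )
    c2 = c * c
    zeta = 2.0 * np.pi * L * c2 / denom_par + 4.0 * np.pi * L * (1.0 - c2) / denom_perp
    return float(zeta) if zeta.ndim == 0 else zeta


def vesicle_axis_force_terms(
    mts: MicrotubuleArray, params: ModelParams
) -> tuple[float, float]:
    """Axis-projected vesicle force terms, normalized by eta_v.

    With continuous vesicle counts ``n_i = rho * L_i`` per rod, the net
    axis-projected force that the motor-hauled cargoes exert on the aster
    when the centrosome moves at speed ``u`` is::

        F_vesicles / eta_v = pull_sum - back_reaction_coeff * u

    where ``pull_sum = 6 pi R_v v_vm sum_i n_i c_i`` (µm^2/s) and
    ``back_reaction_coeff = 6 pi R_v sum_i n_i`` (µm).  Each cargo
    contributes the Stokes drag of its velocity relative to the cytoplasm,
    ``6 pi R_v (v_vm e_i - u x_hat)``, projected on the centring axis.
    """
    stokes = sphere_drag_coefficient(params.vesicle_radius)
    counts = params.vesicle_density * mts.lengths
    pull_sum = stokes * params.vesicle_speed * float(np.dot(counts, mts.axis_cosines))
    back_reaction = stokes * float(np.sum(counts))
    return pull_sum, back_reaction
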