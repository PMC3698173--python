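"""Centring metrics, the centring criterion, and the motor-loading diagnostic.

A run "centres appropriately" when the centrosome has moved at least 300 µm
toward the cell centre within the 45-minute window observed for pronuclear
migration in large embryos.  ``centering_time`` is the first time the
displacement reaches that distance regardless of the window, so runs longer
than 45 minutes still yield a finite centring time for slow parameter sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ModelError
from .simulator import Trajectory

__all__ = [
    "CENTERING_DISPLACEMENT_UM",
    "CENTERING_WINDOW_S",
    "RunSummary",
    "summarize",
    "loading_diagnostic",
]

#: displacement that counts as successful centring (µm)
CENTERING_DISPLACEMENT_UM = 300.0
#: time window within which that displacement must be reached (s)
CENTERING_WINDOW_S = 2700.0


@dataclass
class RunSummary:
    """Derived centring metrics of one trajectory.

    ``mean_speed`` is the displacement at the 45-minute mark divided by
    2700 s (the average centring speed over the observation window); for
    runs shorter than 45 minutes it falls back to final displacement over
    final time.
    ``centering_time`` is the first time displacement reaches 300 µm (linear
    interpolation between samples), or None if it never does;
    ``centered`` additionally requires that to happen within 45 minutes.
    """

    times: np.ndarray
    displacements: np.ndarray
    speeds: np.ndarray
    max_speed: float
    mean_speed: float
    centered: bool
    centering_time: float | None
    far_touch_time: float | None
    near_touch_time: float | None
    far_touch_before_centering: bool

    def displacement_at(self, t: float) -> float:
        """Displacement toward the centre at time t (µm), linearly interpolated."""
        return float(np.interp(t, self.times, self.displacements))

    def speed_at(self, t: float) -> float:
        """Centrosome speed at time t (µm/s), linearly interpolated."""
        return float(np.interp(t, self.times, self.speeds))

    def ramp_time_to_fraction(self, fraction: float) -> float | None:
        """First time the speed reaches ``fraction`` of the run's maximum (s)."""
        if not 0 < fraction <= 1:
            raise ValueError(f"fraction must lie in (0, 1], got {fraction}")
        threshold = fraction * self.max_speed
        idx = np.nonzero(self.speeds >= threshold)[0]
        return float(self.times[idx[0]]) if idx.size else None


def _first_crossing(times: np.ndarray, values: np.ndarray, threshold: float) -> float | None:
    """First time ``values`` reaches ``threshold``, linearly interpolated."""
    idx = np.nonzero(values >= threshold)[0]
    if idx.size == 0:
        return None
    k = int(idx[0])
    if k == 0 or values[k] == threshold:
        return float(times[k])
    frac = (threshold - values[k - 1]) / (values[k] - values[k - 1])
    return float(times[k - 1] + frac * (times[k] - times[k - 1]))


def summarize(traj: Trajectory) -> RunSummary:
    """Compute the centring metrics of a trajectory."""
    if len(traj) == 0:
        raise ModelError("cannot summarize an empty trajectory")
    times = np.asarray(traj.times, dtype=float)
    disp = np.asarray(traj.displacements, dtype=float)
    speeds = np.asarray(traj.centrosome_speeds, dtype=float)

    max_speed = float(np.max(speeds))
    t_end = float(times[-1])
    if t_end >= CENTERING_WINDOW_S:
        mean_speed = float(np.interp(CENTERING_WINDOW_S, times, disp)) / CENTERING_WINDOW_S
    elif t_end > 0:
        mean_speed = float(disp[-1]) / t_end
    else:
        mean_speed = 0.0

    centering_time = _first_crossing(times, disp, CENTERING_DISPLACEMENT_UM)
    centered = centering_time is not None and centering_time <= CENTERING_WINDOW_S
    far_before = traj.far_touch_time is not None and (
        centering_time is None or traj.far_touch_time < centering_time
    )
    return RunSummary(
        times=times,
        displacements=disp,
        speeds=speeds,
        max_speed=max_speed,
        mean_speed=mean_speed,
        centered=centered,
        centering_time=centering_time,
        far_touch_time=traj.far_touch_time,
        near_touch_time=traj.near_touch_time,
        far_touch_before_centering=far_before,
    )


def loading_diagnostic(
    v_left_lab: float, v_right_lab: float, v_centrosome: float
) -> float:
    """Lab-frame cargo-velocity construction that probes motor loading.

    With signed speeds along the centring axis (positive toward the centre),
    ``v_left_lab`` the lab-frame cargo velocity on the near-cortical side,
    ``v_right_lab`` on the far-cortical side and ``v_centrosome`` the
    centrosome velocity, returns::

        delta = (v_centrosome - v_right_lab) - (v_left_lab - v_centrosome)

    i.e. the difference between the motor speeds relative to their
    microtubules on the far and near sides.  Motors running in a
    load-insensitive regime keep the same track speed on both sides, giving
    delta = 0; load-sensitive motors speed up on the unloading far side,
    giving delta > 0.  This is a reconstruction of the published diagnostic
    from its stated sign behaviour; all three inputs are measurable by
    time-lapse microscopy.
    """
    return 2.0 * v_centrosome - v_right_lab - v_left_lab
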