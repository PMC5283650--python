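"""Pelvis-based torso coordinate system and horizontal velocity decomposition.

Individual body motion in conversation is dominated by rigid torso sway,
and the two pelvis-side joints are the most robustly tracked proxy for
it.  Vertical torso speed is small relative to horizontal, so each
person's torso motion is summarised by three horizontal-plane components:

* ``v_par``  — velocity of the pelvis centre along the person's own
  hip-to-hip axis (side-to-side sway),
* ``v_perp`` — velocity perpendicular to that axis (fore-aft),
* ``v_tang`` — tangential speed of a hip about the pelvis centre (twist).

Axes are recomputed every sample from the smoothed hip positions, so the
decomposition is expressed in the person's own frame: invariant to global
translation and equivariant under rotation about the vertical axis.

Convention: y is up; the horizontal plane is x-z.  ``e_par`` points from
the left hip to the right hip; ``e_perp = vertical x e_par``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import JointVelocitySeries
from .skeldata import SkeletonTimeSeries

__all__ = [
    "TorsoVelocitySeries",
    "pelvis_axes",
    "decompose",
    "torso_velocities",
    "vertical_fraction",
]

_HORIZ = (0, 2)  # x and z components
_VERTICAL = np.array([0.0, 1.0, 0.0])

#: Torso joints used for the vertical/horizontal speed diagnostic.
TORSO_JOINTS = ("SpineBase", "SpineMid", "SpineShoulder",
                "ShoulderLeft", "ShoulderRight", "HipLeft", "HipRight")


@dataclass(frozen=True)
class TorsoVelocitySeries:
    """One participant's horizontal torso velocity components (mm/s).

    ``com_speed`` is the horizontal speed of the pelvis centre,
    ``sqrt(v_par^2 + v_perp^2)``.  ``valid`` marks samples where both hip
    joints were usable after gap repair.
    """

    timestamps: np.ndarray
    v_par: np.ndarray
    v_perp: np.ndarray
    v_tang: np.ndarray
    com_speed: np.ndarray
    valid: np.ndarray
    fps: float

    @property
    def n_samples(self) -> int:
        return self.timestamps.shape[0]

    def coords(self) -> np.ndarray:
        """(n, 3) stack of (v_par, v_perp, v_tang)."""
        return np.column_stack([self.v_par, self.v_perp, self.v_tang])


def _horizontal(vec: np.ndarray) -> np.ndarray:
    """Project (..., 3) vectors onto the horizontal (x-z) plane -> (..., 2)."""
    v = np.asarray(vec, dtype=float)
    return v[..., list(_HORIZ)]


def pelvis_axes(left_hip: np.ndarray, right_hip: np.ndarray,
                min_dist: float = 10.0):
    """Horizontal unit axes of the pelvis from the two hip positions.

    ``e_par`` is the normalized horizontal left->right hip vector;
    ``e_perp`` is ``e_par`` rotated 90 degrees in the horizontal plane
    (``vertical x e_par``).  Both are returned as 3-vectors with zero
    vertical component.  Works on single points (3,) or stacks (n, 3).
    Raises if the hips are closer than ``min_dist`` mm after horizontal
    projection (degenerate geometry).
    """
    lh = np.asarray(left_hip, dtype=float)
    rh = np.asarray(right_hip, dtype=float)
    d = rh - lh
    d[..., 1] = 0.0
    norm = np.linalg.norm(d, axis=-1)
    if np.any(norm <= min_dist):
        raise ValueError("degenerate pelvis geometry: hips coincide after "
                         "horizontal projection")
    e_par = d / norm[..., None]
    e_perp = np.cross(np.broadcast_to(_VERTICAL, e_par.shape), e_par)
    return e_par, e_perp


def decompose(left_hip_v: np.ndarray, right_hip_v: np.ndarray, axes):
    """Split hip velocities into (v_par, v_perp, v_tang).

    The pelvis-centre velocity is the mean of the two hip velocities
    projected to the horizontal plane; ``v_par``/``v_perp`` are its
    components along the pelvis axes.  ``v_tang`` is the tangential hip
    speed about the centre: half the horizontal hip-velocity difference
    (right minus left) along ``e_perp``.
    """
    e_par, e_perp = axes
    lv = np.asarray(left_hip_v, dtype=float)
    rv = np.asarray(right_hip_v, dtype=float)
    c = 0.5 * (lv + rv)
    c[..., 1] = 0.0
    diff = rv - lv
    diff[..., 1] = 0.0
    v_par = np.sum(c * e_par, axis=-1)
    v_perp = np.sum(c * e_perp, axis=-1)
    v_tang = 0.5 * np.sum(diff * e_perp, axis=-1)
    return v_par, v_perp, v_tang


def torso_velocities(smoothed: SkeletonTimeSeries,
                     velocities: JointVelocitySeries) -> TorsoVelocitySeries:
    """Per-sample torso decomposition for one participant.

    ``smoothed`` supplies the hip *positions* that define the axes;
    ``velocities`` supplies the hip velocities (both on the same grid).
    """
    lh_p = smoothed.joint_positions("HipLeft")
    rh_p = smoothed.joint_positions("HipRight")
    axes = pelvis_axes(lh_p, rh_p)
    lv = velocities.joint_velocity("HipLeft")
    rv = velocities.joint_velocity("HipRight")
    v_par, v_perp, v_tang = decompose(lv, rv, axes)
    com_speed = np.hypot(v_par, v_perp)
    il = velocities.joint_index("HipLeft")
    ir = velocities.joint_index("HipRight")
    valid = velocities.valid[:, il] & velocities.valid[:, ir]
    return TorsoVelocitySeries(
        timestamps=velocities.timestamps, v_par=v_par, v_perp=v_perp,
        v_tang=v_tang, com_speed=com_speed, valid=valid, fps=velocities.fps)


def vertical_fraction(v: JointVelocitySeries,
                      joints=TORSO_JOINTS) -> float:
    """RMS vertical / RMS horizontal torso speed (diagnostic ratio).

    Pooled over the given torso joints and all samples.  Raises if the
    horizontal RMS is zero (ratio undefined).
    """
    idx = [v.joint_index(j) for j in joints]
    vel = v.velocities[:, idx, :]
    vert = vel[..., 1]
    horiz = np.hypot(vel[..., 0], vel[..., 2])
    rms_h = np.sqrt(np.mean(horiz ** 2))
    if rms_h == 0:
        raise ValueError("horizontal torso RMS speed is zero; "
                         "vertical fraction undefined")
    return float(np.sqrt(np.mean(vert ** 2)) / rms_h)
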