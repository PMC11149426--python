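"""Rotation kinematics in Euler-Rodrigues rotation-vector form.

3D eye orientations are represented as rotation vectors ``r = tan(theta/2) * n``
for a rotation of angle ``theta`` about the unit axis ``n``; components are in
"half-radian" (rad/2) units.  In the head-fixed, right-handed lab frame the x
axis is frontal (cyclo-torsion, clockwise positive), y is the horizontal axis
(vertical rotations, downward positive) and z is the vertical axis (horizontal
rotations, leftward positive).  The zero vector is the straight-ahead
reference orientation.

Rotation composition is non-commutative; the angular velocity ``omega`` (rad/s,
about the momentary rotation axis) and the coordinate velocity ``rdot = dr/dt``
are related by a nonlinear map that contains the vector cross product.  All
functions here are exact (no small-angle approximations) and total on the
oculomotor range; orientations approaching a rotation angle of pi, where the
tan(theta/2) chart degenerates, are rejected rather than regularized.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "omega_from_orientation_rate",
    "orientation_rate_from_omega",
    "compose",
    "inverse",
    "relative_rotation",
    "rotation_angle_deg",
    "angles_from_rotvec",
    "rotvec_from_angles",
    "half_angle_tilt",
    "rotation_matrix",
]

# denominators in the composition rules vanish when two rotations compose to
# an angle of exactly pi; the oculomotor range (< ~30 deg) never gets close
_DEGENERATE_TOL = 1e-12


def _as_vec3(x, name: str) -> np.ndarray:
    v = np.asarray(x, dtype=float)
    if v.shape != (3,):
        raise ValueError(f"{name} must be a 3-vector, got shape {v.shape}")
    if not np.all(np.isfinite(v)):
        raise ValueError(f"{name} must be finite, got {v}")
    return v


def omega_from_orientation_rate(r, rdot) -> np.ndarray:
    """Angular velocity (rad/s) from orientation ``r`` and its rate ``rdot``.

    omega = 2 (rdot + r x rdot) / (1 + ||r||^2)
    """
    r = _as_vec3(r, "r")
    rdot = _as_vec3(rdot, "rdot")
    return 2.0 * (rdot + np.cross(r, rdot)) / (1.0 + r @ r)


def orientation_rate_from_omega(r, omega) -> np.ndarray:
    """Coordinate velocity ``rdot`` from orientation ``r`` and angular velocity.

    2 rdot = omega + omega x r + (omega . r) r

    Exact algebraic inverse of :func:`omega_from_orientation_rate`.
    """
    r = _as_vec3(r, "r")
    w = _as_vec3(omega, "omega")
    return 0.5 * (w + np.cross(w, r) + (w @ r) * r)


def compose(r_b, r_a) -> np.ndarray:
    """Rotation-vector product: rotation ``r_a`` followed by ``r_b``.

    (r_b + r_a + r_b x r_a) / (1 - r_b . r_a)

    Matches the vector part over scalar part of the unit-quaternion product
    q_b (x) q_a.  Non-commutative for non-parallel arguments.
    """
    a = _as_vec3(r_a, "r_a")
    b = _as_vec3(r_b, "r_b")
    den = 1.0 - b @ a
    if abs(den) < _DEGENERATE_TOL:
        raise ValueError(
            "degenerate composition: rotations compose to an angle of pi"
        )
    return (b + a + np.cross(b, a)) / den


def inverse(r) -> np.ndarray:
    """Inverse rotation: compose(r, inverse(r)) = 0."""
    return -_as_vec3(r, "r")


def relative_rotation(r_on, r_g) -> np.ndarray:
    """The rotation q that carries orientation ``r_on`` onto ``r_g``.

    q = r_g o r_on^-1 = (r_g - r_on + r_on x r_g) / (1 + r_on . r_g)

    satisfying compose(q, r_on) = r_g.  Used to express a saccade goal
    relative to the current fixation, e.g. for amplitude bookkeeping in the
    chained paradigms.
    """
    a = _as_vec3(r_on, "r_on")
    g = _as_vec3(r_g, "r_g")
    den = 1.0 + a @ g
    if abs(den) < _DEGENERATE_TOL:
        raise ValueError("degenerate relative rotation (angle pi)")
    return (g - a + np.cross(a, g)) / den


def rotation_angle_deg(r) -> float:
    """Total rotation angle of a rotation vector, in degrees."""
    r = _as_vec3(r, "r")
    return float(np.degrees(2.0 * np.arctan(np.linalg.norm(r))))


def angles_from_rotvec(r) -> tuple[float, float]:
    """Gaze angles (azimuth theta_H, elevation phi_V) in deg from ``r``.

    theta_H = -2 arctan(r_z)  (rightward positive)
    phi_V   = -2 arctan(r_y)  (upward positive)
    """
    r = _as_vec3(r, "r")
    theta_h = -2.0 * np.degrees(np.arctan(r[2]))
    phi_v = -2.0 * np.degrees(np.arctan(r[1]))
    return float(theta_h), float(phi_v)


def rotvec_from_angles(theta_h: float, phi_v: float, r_x: float = 0.0) -> np.ndarray:
    """Rotation vector from gaze angles (deg); torsion ``r_x`` given explicitly.

    Exact inverse of :func:`angles_from_rotvec` on the (theta_H, phi_V)
    subspace.  The torsional component is not determined by gaze direction
    alone (that is the content of Donders'/Listing's law) and defaults to 0.
    """
    r_z = -np.tan(np.radians(theta_h) / 2.0)
    r_y = -np.tan(np.radians(phi_v) / 2.0)
    return np.array([r_x, r_y, r_z], dtype=float)


def half_angle_tilt(phi0_deg: float) -> float:
    """Half-angle rule: tilt (deg) of omega out of Listing's plane.

    For a horizontal movement (rdot along z) made from a vertical
    eccentricity ``phi0``, i.e. r_on = tan(phi0/2) * y_hat, the angular
    velocity axis tilts out of the plane of rdot by exactly phi0/2.
    """
    return float(phi0_deg) / 2.0


def rotation_matrix(r) -> np.ndarray:
    """3x3 rotation matrix of the rotation vector ``r`` (acts on eye-frame
    coordinates to give head-frame coordinates)."""
    r = _as_vec3(r, "r")
    n2 = r @ r
    rx, ry, rz = r
    K = np.array([[0.0, -rz, ry], [rz, 0.0, -rx], [-ry, rx, 0.0]])
    return np.eye(3) + (2.0 / (1.0 + n2)) * (K + K @ K)
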