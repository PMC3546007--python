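"""Rotation-group helpers for the multibody solver.

Rotation vectors follow the axis-angle (Rodrigues) convention; all angles in
radians.  The left-Jacobian inverse is needed to differentiate the matrix
logarithm of a relative rotation with respect to a body-frame increment.
"""

from __future__ import annotations

import numpy as np

_EPS = 1e-12


def skew(v: np.ndarray) -> np.ndarray:
    """Cross-product matrix: skew(v) @ u == v x u."""
    return np.array(
        [
            [0.0, -v[2], v[1]],
            [v[2], 0.0, -v[0]],
            [-v[1], v[0], 0.0],
        ]
    )


def exp_so3(w: np.ndarray) -> np.ndarray:
    """Rodrigues formula: rotation matrix for rotation vector w."""
    theta = float(np.linalg.norm(w))
    K = skew(w)
    if theta < 1e-8:
        # second-order series, exact enough at this magnitude
        return np.eye(3) + K + 0.5 * (K @ K)
    a = np.sin(theta) / theta
    b = (1.0 - np.cos(theta)) / theta**2
    return np.eye(3) + a * K + b * (K @ K)


def log_so3(R: np.ndarray) -> np.ndarray:
    """Rotation vector of R (inverse of exp_so3); |result| <= pi."""
    tr = np.clip((np.trace(R) - 1.0) / 2.0, -1.0, 1.0)
    theta = float(np.arccos(tr))
    if theta < 1e-8:
        # antisymmetric part is exact to O(theta^3)
        return 0.5 * np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]])
    if theta > np.pi - 1e-6:
        # near pi: use the symmetric part
        A = (R + np.eye(3)) / 2.0
        axis = np.sqrt(np.maximum(np.diag(A), 0.0))
        # fix signs from off-diagonals
        i = int(np.argmax(axis))
        if axis[i] > _EPS:
            s = np.array(
                [A[0, i], A[1, i], A[2, i]]
            )
            axis = s / axis[i]
            axis = axis / np.linalg.norm(axis)
        return theta * axis
    w = np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]])
    return theta / (2.0 * np.sin(theta)) * w


def left_jacobian_inv(psi: np.ndarray) -> np.ndarray:
    """Inverse left Jacobian of SO(3): d/dw log(exp(w) exp(psi)) at w=0."""
    theta = float(np.linalg.norm(psi))
    K = skew(psi)
    if theta < 1e-6:
        return np.eye(3) - 0.5 * K + (1.0 / 12.0) * (K @ K)
    c = 1.0 / theta**2 - (1.0 + np.cos(theta)) / (2.0 * theta * np.sin(theta))
    return np.eye(3) - 0.5 * K + c * (K @ K)


def right_jacobian_inv(psi: np.ndarray) -> np.ndarray:
    """d/dw log(exp(psi) exp(w)) at w=0."""
    return left_jacobian_inv(-psi)


def rotation_about(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n < _EPS:
        raise ValueError("zero rotation axis")
    return exp_so3(axis / n * angle)
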