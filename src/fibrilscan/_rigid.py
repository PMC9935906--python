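"""Low-level rigid-body mathematics (pure arrays, no model types)."""

from __future__ import annotations

import numpy as np


def kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid transform mapping ``mobile`` onto ``target``.

    Returns ``(rotation, translation, rmsd)`` with
    ``target ≈ mobile @ rotation.T + translation``.  Improper (mirror)
    solutions are corrected to a proper rotation (det = +1).

    Raises
    ------
    ValueError
        if the paired lists differ in length, have fewer than 3 points, or
        the mobile set is degenerate (collinear).
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(target, dtype=float)
    if P.shape != Q.shape:
        raise ValueError(f"paired coordinate sets differ in shape: {P.shape} vs {Q.shape}")
    if P.ndim != 2 or P.shape[1] != 3 or P.shape[0] < 3:
        raise ValueError("need at least 3 paired 3-D points")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    s = np.linalg.svd(P0, compute_uv=False)
    if s[1] < 1e-8 * max(s[0], 1.0):
        raise ValueError("degenerate (collinear) coordinates: superposition is not unique")
    H = P0.T @ Q0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    diff = (P @ R.T + t) - Q
    rmsd = float(np.sqrt((diff * diff).sum() / P.shape[0]))
    return R, t, rmsd


def rotation_axis_angle(R: np.ndarray) -> tuple[np.ndarray, float]:
    """Axis (unit vector) and angle in radians of a proper rotation.

    For near-identity rotations the axis is ill-defined; returns the z axis
    with angle 0.
    """
    cos_theta = np.clip((np.trace(R) - 1.0) / 2.0, -1.0, 1.0)
    theta = float(np.arccos(cos_theta))
    if theta < 1e-9:
        return np.array([0.0, 0.0, 1.0]), 0.0
    # antisymmetric part encodes axis*sin(theta)
    ax = np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]])
    n = np.linalg.norm(ax)
    if n < 1e-12:  # theta ~ pi
        # axis from symmetric part
        M = (R + np.eye(3)) / 2.0
        axis = np.sqrt(np.clip(np.diag(M), 0.0, None))
        axis /= max(np.linalg.norm(axis), 1e-12)
        return axis, theta
    return ax / n, theta


def mean_rotation(rotations: list[np.ndarray]) -> np.ndarray:
    """Chordal mean of proper rotations (projection of the matrix average)."""
    M = np.mean(np.stack(rotations), axis=0)
    U, _, Vt = np.linalg.svd(M)
    d = np.sign(np.linalg.det(U @ Vt))
    return U @ np.diag([1.0, 1.0, d]) @ Vt


def rotation_about_axis(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    a = np.asarray(axis, dtype=float)
    a = a / np.linalg.norm(a)
    K = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    return np.eye(3) + np.sin(angle_rad) * K + (1 - np.cos(angle_rad)) * (K @ K)
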