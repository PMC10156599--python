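"""Organoid rotation analysis: rigid-body decomposition, classification,
and internal-rearrangement overlap parameter.

Per-frame nuclear centroid clouds are decomposed into a global rigid
rotation about the organoid centroid (least-squares orthogonal / Kabsch
fit) plus internal residual motion.  The angular velocity classifies
organoids as rotating (> 0.03 cycles/h mean angular speed) or static; the
residual trajectories yield the overlap parameter Q(τ) — the fraction of
cells displaced less than a cutoff d₀ over lag τ — and its relaxation time
τ* (Q = 1/2 crossing), which quantifies internal fluidity independently of
the rotation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation
from scipy.spatial import cKDTree

__all__ = [
    "RigidMotion",
    "rigid_motion_3d",
    "classify_rotation",
    "overlap_parameter",
    "default_overlap_cutoff",
    "clouds_from_table",
]

ROTATION_THRESHOLD = 0.03      # cycles/h, strict ("larger than")


@dataclass
class RigidMotion:
    """Rigid-rotation decomposition of an organoid recording.

    rotations : per-step 3×3 matrices R(t→t+1) about the centroid
    omega : (T−1, 3) angular velocity components, cycles/h
    angular_speed : (T−1,) |ω|, cycles/h
    residuals : (T, N, 3) positions with cumulative rigid motion removed
                (body frame of the first time point), μm
    """

    rotations: np.ndarray
    omega: np.ndarray
    angular_speed: np.ndarray
    residuals: np.ndarray
    dt: float    # minutes

    @property
    def mean_speed(self) -> float:
        return float(self.angular_speed.mean())


def clouds_from_table(df: pd.DataFrame) -> np.ndarray:
    """(T, N, 3) array from a (frame, cell_id, x_um, y_um, z_um) table;
    requires every cell present in every frame."""
    piv = df.pivot_table(index="frame", columns="cell_id",
                         values=["x_um", "y_um", "z_um"])
    if piv.isna().any().any():
        raise ValueError("cells must be present in every frame")
    t = len(piv)
    n = df["cell_id"].nunique()
    out = np.empty((t, n, 3))
    for k, axis in enumerate(["x_um", "y_um", "z_um"]):
        out[:, :, k] = piv[axis].to_numpy()
    return out


def _kabsch(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation matrix minimising |R a_i − b_i|² for centred clouds."""
    h = a.T @ b
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    return vt.T @ corr @ u.T


def rigid_motion_3d(clouds: np.ndarray, dt: float) -> RigidMotion:
    """Per-step optimal rigid rotation and residual internal motion.

    ``clouds`` is (T, N, 3) with id-matched points; ``dt`` the frame
    interval in minutes.  Angular velocity is the axis–angle of each
    consecutive rotation divided by dt, reported in cycles/h.
    """
    clouds = np.asarray(clouds, float)
    if clouds.ndim != 3 or clouds.shape[2] != 3:
        raise ValueError("clouds must be (T, N, 3)")
    t_n, n = clouds.shape[:2]
    if n < 4:
        raise ValueError("need >= 4 points for a rigid fit")
    cen = clouds.mean(axis=1)
    centred = clouds - cen[:, None, :]
    if np.linalg.matrix_rank(centred[0]) < 3:
        raise ValueError("degenerate (coplanar) cloud")

    rotations = np.empty((t_n - 1, 3, 3))
    omega = np.empty((t_n - 1, 3))
    cum = np.eye(3)
    residuals = np.empty_like(centred)
    residuals[0] = centred[0]
    for t in range(t_n - 1):
        r = _kabsch(centred[t], centred[t + 1])
        rotations[t] = r
        rotvec = Rotation.from_matrix(r).as_rotvec()      # rad over dt
        omega[t] = rotvec / dt * 60.0 / (2 * np.pi)       # cycles/h
        cum = r @ cum
        residuals[t + 1] = centred[t + 1] @ cum           # back to body frame
    speed = np.linalg.norm(omega, axis=1)
    return RigidMotion(rotations, omega, speed, residuals, dt)


def classify_rotation(angular_speed: np.ndarray | float,
                      threshold: float = ROTATION_THRESHOLD) -> str:
    """'rotating' when the mean angular speed strictly exceeds the
    threshold (0.03 cycles/h), 'non-rotating' otherwise."""
    mean_speed = float(np.mean(angular_speed))
    return "rotating" if mean_speed > threshold else "non-rotating"


def default_overlap_cutoff(cloud: np.ndarray) -> float:
    """Half the mean nearest-neighbour distance of one frame's cloud."""
    tree = cKDTree(cloud)
    d, _ = tree.query(cloud, k=2)
    return float(0.5 * d[:, 1].mean())


def overlap_parameter(residuals: np.ndarray, d0: float, dt: float,
                      ) -> tuple[pd.DataFrame, float]:
    """Overlap parameter Q(τ) of residual (rotation-free) trajectories.

    Q(τ) = fraction of (cell, t) pairs with |Δr(τ)| < d₀, averaged over t;
    τ* is the Q = 1/2 crossing (linear interpolation between lags), inf when
    Q never decays that far.  Returns (table with tau_h, Q; tau_star_h).
    """
    if d0 <= 0:
        raise ValueError("cutoff d0 must be positive")
    residuals = np.asarray(residuals, float)
    t_n = residuals.shape[0]
    taus = np.arange(1, t_n)
    q = np.empty(len(taus))
    for k, tau in enumerate(taus):
        d = residuals[tau:] - residuals[:-tau]
        disp = np.linalg.norm(d, axis=2)
        q[k] = float((disp < d0).mean())
    tau_h = taus * dt / 60.0

    tau_star = np.inf
    below = np.nonzero(q <= 0.5)[0]
    if len(below):
        i = below[0]
        if i == 0:
            tau_star = tau_h[0]
        else:
            q1, q2 = q[i - 1], q[i]
            t1, t2 = tau_h[i - 1], tau_h[i]
            tau_star = t1 + (q1 - 0.5) * (t2 - t1) / (q1 - q2)
    return pd.DataFrame({"tau_h": tau_h, "Q": q}), float(tau_star)
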