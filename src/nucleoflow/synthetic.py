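"""Synthetic monolayers, organoids and tracers with planted ground truth.

The monolayer generator is a phenomenological active-particle model: cells
are self-propelled soft disks in a periodic box, with Vicsek-type heading
alignment controlling the jammed → flocking transition.  Each cell carries a
nucleus whose projected area responds to the local tissue strain rate
through an iso-stress nucleus/cytoplasm composite with a planted moduli
ratio R = E_N/E_CY and nuclear area fraction β — the areal strain of the
nucleus is attenuated by s = 1/(β + (1−β)R) relative to the cell — plus an
intrinsic Ornstein–Uhlenbeck fluctuation whose stationary variance σ² and
correlation time τ_c plant the mean-square-strain parameters γ̇₀ = 2σ²/τ_c
and τ_c exactly.

Rendering produces realistic fluorescence frames (anisotropic Gaussian
nuclei, PSF blur, smooth illumination gradient, shot + read noise) so the
whole segmentation/tracking/PIV pipeline can be validated against the
planted state.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .segtrack import FrameStack
from .piv import divergence_on_grid

__all__ = [
    "MonolayerConfig",
    "OpticsConfig",
    "GroundTruth",
    "simulate_monolayer",
    "render_frames",
    "simulate_stretch_experiment",
    "simulate_organoid",
    "simulate_tracer_walk",
    "correlated_velocity_sample",
]


# ---------------------------------------------------------------------------
# configs / ground truth
# ---------------------------------------------------------------------------


@dataclass
class MonolayerConfig:
    """Conditions of a simulated monolayer experiment.

    Distances in μm, times in minutes except the OU correlation time
    ``ou_tau`` which is in hours (the paper's strain-dynamics time unit).
    ``regime`` is a convenience label; the kinematics are fully determined by
    alignment_strength / self_propulsion_speed / noise_amplitude.
    """

    n_cells: int = 400
    box_size: float = 280.0          # μm; default → ~14 μm spacing at n=400
    dt: float = 10.0                 # min between stored frames
    n_frames: int = 60
    regime: str = "flocking"
    alignment_strength: float = 0.8
    self_propulsion_speed: float = 0.3   # μm/min
    noise_amplitude: float = 0.15
    moduli_ratio: float = 3.0        # planted R = E_N/E_CY
    beta: float = 0.25               # nuclear area fraction
    mean_nuclear_area: float = 60.0  # μm²
    ou_sigma: float = 0.10           # stationary sd of intrinsic area strain
    ou_tau: float = 1.5              # h
    n_warmup: int = 20               # unrecorded frames to reach steady state
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 2:
            raise ValueError("n_cells must be >= 2")
        if not 0 < self.beta < 1:
            raise ValueError("beta must lie in (0, 1)")
        if self.moduli_ratio <= 0:
            raise ValueError("moduli_ratio must be positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @classmethod
    def jammed(cls, **kw) -> "MonolayerConfig":
        """Kinetically arrested monolayer: weak uncoordinated motility."""
        kw.setdefault("regime", "jammed")
        kw.setdefault("alignment_strength", 0.0)
        kw.setdefault("self_propulsion_speed", 0.06)
        kw.setdefault("noise_amplitude", 1.0)
        return cls(**kw)

    @classmethod
    def flocking(cls, **kw) -> "MonolayerConfig":
        """Fluidised monolayer: aligned, fast collective migration."""
        kw.setdefault("regime", "flocking")
        return cls(**kw)


@dataclass
class OpticsConfig:
    """Rendering parameters emulating widefield fluorescence acquisition."""

    pixel_size: float = 0.65         # μm
    psf_sigma: float = 0.6           # μm
    background_gradient_amplitude: float = 0.15   # fraction of peak
    photon_scale: float = 120.0      # counts per μm² of nucleus; the default
                                     # puts the in-nucleus pixel SNR near 5

    read_noise_sigma: float = 3.0    # counts
    bit_depth: int = 16
    background_level: float = 40.0   # counts, uniform dark background

    def __post_init__(self) -> None:
        if self.pixel_size <= 0 or self.psf_sigma <= 0:
            raise ValueError("pixel_size and psf_sigma must be positive")


@dataclass
class GroundTruth:
    """Planted simulation state.

    positions/velocities: (T, N, 2) μm and μm/min; areas: (T, N) μm²;
    thetas: (T, N) rad; cell_strain_rate: (T, N) min⁻¹, the local tissue
    strain rate each nucleus was driven with (γ̇_C at the cell).  Velocities
    are forward differences, i.e. velocity[t] is the mean velocity on the
    interval t → t+1 (PIV semantics); the last frame repeats the previous
    one.
    """

    positions: np.ndarray
    velocities: np.ndarray
    areas: np.ndarray
    thetas: np.ndarray
    cell_strain_rate: np.ndarray
    aspect: np.ndarray                # (N,) nucleus axis ratio >= 1
    config: MonolayerConfig

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_cells(self) -> int:
        return self.positions.shape[1]

    @property
    def planted_gamma0(self) -> float:
        """Intrinsic MSS short-time strain rate, h⁻¹ (= 2σ²/τ_c)."""
        c = self.config
        return 2.0 * c.ou_sigma ** 2 / c.ou_tau

    @property
    def planted_tau_c(self) -> float:
        return self.config.ou_tau

    @property
    def strain_attenuation(self) -> float:
        """Planted slope s = γ̇_N/γ̇_C = 1/(β + (1−β)R)."""
        c = self.config
        return 1.0 / (c.beta + (1.0 - c.beta) * c.moduli_ratio)

    def to_dataframe(self) -> pd.DataFrame:
        t, n = self.positions.shape[:2]
        frames = np.repeat(np.arange(t), n)
        cells = np.tile(np.arange(n), t)
        return pd.DataFrame({
            "frame": frames,
            "cell_id": cells,
            "x_um": self.positions[..., 0].ravel(),
            "y_um": self.positions[..., 1].ravel(),
            "vx": self.velocities[..., 0].ravel(),
            "vy": self.velocities[..., 1].ravel(),
            "area_um2": self.areas.ravel(),
            "theta_rad": self.thetas.ravel(),
        })

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def to_trackset(self):
        """Ideal TrackSet built directly from the planted state (no imaging):
        one perfectly tracked trajectory per cell.  Positions are unwrapped
        across the periodic box so finite differences are meaningful."""
        from .segtrack import TrackSet

        t, n = self.positions.shape[:2]
        box = self.config.box_size
        steps = np.diff(self.positions, axis=0)
        steps -= box * np.round(steps / box)
        unwrapped = np.concatenate(
            [self.positions[:1], self.positions[0] + np.cumsum(steps, axis=0)])
        df = pd.DataFrame({
            "frame": np.repeat(np.arange(t), n),
            "track_id": np.tile(np.arange(n), t),
            "x_um": unwrapped[..., 0].ravel(),
            "y_um": unwrapped[..., 1].ravel(),
            "area_um2": self.areas.ravel(),
            "theta_rad": self.thetas.ravel(),
            "perimeter_um": 2 * np.sqrt(np.pi * self.areas.ravel()),
            "J": self.areas.ravel() * 0 + 1.0,
            "quality_flag": False,
        })
        return TrackSet(df, pixel_size=1.0, dt=self.config.dt)


# ---------------------------------------------------------------------------
# monolayer simulation
# ---------------------------------------------------------------------------


def _wrap(x: np.ndarray, box: float) -> np.ndarray:
    return np.mod(x, box)


def kernel_velocity_grid(positions: np.ndarray, velocities: np.ndarray,
                         box: float, spacing: float,
                         ) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Gaussian-kernel interpolation of scattered velocities onto a grid.

    Returns (x_centres, u, v, spacing); grids are periodic over the box.
    This is the coarse-graining the simulator uses to compute the local
    tissue strain rate, and the one the analysis can reuse on ground-truth
    tracks, keeping the two self-consistent.
    """
    n_grid = max(4, int(round(box / spacing)))
    h = box / n_grid
    centres = (np.arange(n_grid) + 0.5) * h
    sig = h
    # periodic distances position -> grid nodes, separable kernel
    dx = positions[:, 0][:, None] - centres[None, :]
    dy = positions[:, 1][:, None] - centres[None, :]
    dx -= box * np.round(dx / box)
    dy -= box * np.round(dy / box)
    wx = np.exp(-0.5 * (dx / sig) ** 2)
    wy = np.exp(-0.5 * (dy / sig) ** 2)
    # weight of particle p on node (i=y, j=x): wy[p,i]*wx[p,j]
    wsum = np.einsum("pi,pj->ij", wy, wx)
    u = np.einsum("p,pi,pj->ij", velocities[:, 0], wy, wx)
    v = np.einsum("p,pi,pj->ij", velocities[:, 1], wy, wx)
    wsum = np.clip(wsum, 1e-12, None)
    return centres, u / wsum, v / wsum, h


def _sample_bilinear_periodic(field: np.ndarray, pts: np.ndarray, h: float,
                              box: float) -> np.ndarray:
    """Bilinear sampling of a periodic grid field at scattered points."""
    n = field.shape[0]
    gx = pts[:, 0] / h - 0.5
    gy = pts[:, 1] / h - 0.5
    x0 = np.floor(gx).astype(int)
    y0 = np.floor(gy).astype(int)
    fx = gx - x0
    fy = gy - y0
    x0m, x1m = x0 % n, (x0 + 1) % n
    y0m, y1m = y0 % n, (y0 + 1) % n
    return ((1 - fy) * (1 - fx) * field[y0m, x0m]
            + (1 - fy) * fx * field[y0m, x1m]
            + fy * (1 - fx) * field[y1m, x0m]
            + fy * fx * field[y1m, x1m])


def local_strain_rate(positions: np.ndarray, velocities: np.ndarray,
                      box: float, spacing: float = 14.0) -> np.ndarray:
    """Local tissue strain rate γ̇_C at each cell: divergence of the
    kernel-interpolated velocity field sampled at the cell positions."""
    _, u, v, h = kernel_velocity_grid(positions, velocities, box, spacing)
    div = divergence_on_grid(u, v, h, periodic=True)
    return _sample_bilinear_periodic(div, positions, h, box)


def _neighbour_displacements(pos: np.ndarray, box: float, cutoff: float):
    """Pairwise displacement vectors within cutoff (periodic); dense but
    vectorised — adequate for the few hundred cells used here."""
    d = pos[None, :, :] - pos[:, None, :]
    d -= box * np.round(d / box)
    r2 = (d ** 2).sum(-1)
    return d, r2


def simulate_monolayer(cfg: MonolayerConfig) -> GroundTruth:
    """Simulate a confluent monolayer with deformable nuclei.

    Self-propelled soft disks with Vicsek alignment in a periodic box.  At
    each stored frame the realised cell velocities are coarse-grained, their
    divergence gives the local tissue strain rate γ̇_C for each cell, and
    nuclear areas are updated multiplicatively with the attenuated strain
    s·γ̇_C (s = 1/(β + (1−β)R)) plus an exact-discretisation OU intrinsic
    term.
    """
    rng = np.random.default_rng(cfg.seed)
    n, box = cfg.n_cells, cfg.box_size
    spacing = box / np.sqrt(n)
    r_int = 0.5 * spacing            # soft-disk radius: lattice just at contact
    align_radius = 1.6 * spacing

    # near-triangular initial packing with jitter
    n_side = int(np.ceil(np.sqrt(n)))
    gx, gy = np.meshgrid(np.arange(n_side), np.arange(n_side))
    pos = np.column_stack([gx.ravel(), gy.ravel()]).astype(float)[:n]
    pos[:, 0] += 0.5 * (np.arange(len(pos)) // n_side % 2)
    pos = _wrap(pos * (box / n_side) + rng.normal(0, 0.15 * spacing, (n, 2)), box)

    heading = rng.uniform(0, 2 * np.pi, n)
    v0, a, eta = cfg.self_propulsion_speed, cfg.alignment_strength, cfg.noise_amplitude
    k_rep = 0.2                       # repulsion mobility·stiffness, min⁻¹

    substeps = 4
    h_dt = cfg.dt / substeps

    s_att = 1.0 / (cfg.beta + (1.0 - cfg.beta) * cfg.moduli_ratio)
    tau_min = cfg.ou_tau * 60.0
    rho = np.exp(-cfg.dt / tau_min)
    ou = rng.normal(0, cfg.ou_sigma, n)
    base_area = cfg.mean_nuclear_area * np.exp(rng.normal(0, 0.12, n))
    aspect = np.clip(rng.normal(1.3, 0.12, n), 1.0, None)
    thetas0 = rng.uniform(0, np.pi, n)

    positions = np.empty((cfg.n_frames, n, 2))
    velocities = np.empty((cfg.n_frames, n, 2))
    areas = np.empty((cfg.n_frames, n))
    thetas = np.empty((cfg.n_frames, n))
    strain = np.zeros((cfg.n_frames, n))

    log_mech = np.zeros(n)
    theta_n = thetas0.copy()

    for t in range(-cfg.n_warmup, cfg.n_frames):
        if t >= 0:
            positions[t] = pos
            areas[t] = base_area * np.exp(log_mech) * (1.0 + ou)
            thetas[t] = theta_n

        start = pos.copy()
        for _ in range(substeps):
            if v0 == 0:
                break  # static limit: no motion at all
            vel = v0 * np.column_stack([np.cos(heading), np.sin(heading)])
            d, r2 = _neighbour_displacements(pos, box, r_int)
            r = np.sqrt(r2)
            overlap = np.clip(2 * r_int - r, 0, None)
            np.fill_diagonal(overlap, 0.0)
            fmag = np.where(r > 1e-9, overlap / np.where(r > 1e-9, r, 1.0), 0.0)
            force = -(d * fmag[..., None]).sum(axis=1)
            vel = vel + k_rep * force
            pos = _wrap(pos + vel * h_dt, box)
            # Vicsek alignment on realised headings
            if a > 0:
                d, r2 = _neighbour_displacements(pos, box, align_radius)
                nb = r2 < align_radius ** 2
                ex = nb @ np.cos(heading)
                ey = nb @ np.sin(heading)
                mean_ang = np.arctan2(ey, ex)
                delta = np.angle(np.exp(1j * (mean_ang - heading)))
                heading = heading + a * delta * (h_dt / cfg.dt)
            heading = heading + eta * np.sqrt(h_dt / cfg.dt) * rng.normal(0, 1, n)

        disp = pos - start
        disp -= box * np.round(disp / box)
        vel_frame = disp / cfg.dt

        if v0 > 0:
            gdot_c = local_strain_rate(start, vel_frame, box)
        else:
            gdot_c = np.zeros(n)
        if t >= 0:
            velocities[t] = vel_frame
            strain[t] = gdot_c
        log_mech = log_mech + s_att * gdot_c * cfg.dt
        ou = rho * ou + cfg.ou_sigma * np.sqrt(1 - rho ** 2) * rng.normal(0, 1, n)
        theta_n = np.mod(theta_n + rng.normal(0, 0.05, n), np.pi)

    return GroundTruth(positions, velocities, areas, thetas, strain,
                       aspect, cfg)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def render_frames(truth: GroundTruth, optics: OpticsConfig | None = None,
                  seed: int | None = None) -> FrameStack:
    """Render a ground truth into a calibrated fluorescence stack.

    Each nucleus is a uniformly filled anisotropic ellipse of the nucleus's
    area and orientation with PSF-smoothed (erf-profile) edges, so the
    half-maximum footprint is the true area and the integrated intensity is
    proportional to area — the flat chromatin fill with diffraction-limited
    edges seen in real H2B images.  The box is periodic, so nuclei wrap
    around the frame edges.  A smooth multiplicative illumination gradient,
    Poisson shot noise and Gaussian read noise complete the image.
    """
    optics = optics or OpticsConfig()
    cfg = truth.config
    if truth.n_frames < 1:
        raise ValueError("empty ground truth")
    px = optics.pixel_size
    n_px = int(round(cfg.box_size / px))
    mean_diam_px = 2 * np.sqrt(cfg.mean_nuclear_area / np.pi) / px
    if n_px < 2 * mean_diam_px or mean_diam_px < 2:
        raise ValueError(
            "pixel grid smaller than 2 nuclei diameters (or nuclei "
            "unresolvable at this pixel size)")
    rng = np.random.default_rng(cfg.seed + 7919 if seed is None else seed)

    yy, xx = np.mgrid[0:n_px, 0:n_px]
    gx = (xx + 0.5) * px / cfg.box_size - 0.5
    gy = (yy + 0.5) * px / cfg.box_size - 0.5
    illum = 1.0 + optics.background_gradient_amplitude * (
        0.8 * gx + 0.6 * gy + 0.5 * (gx * gy))

    frames = np.empty((truth.n_frames, n_px, n_px), dtype=np.uint16)
    max_val = 2 ** optics.bit_depth - 1
    s_psf = optics.psf_sigma / px
    # chromatin content is conserved: each nucleus carries a fixed total
    # intensity (photon_scale × its baseline area), so its mean brightness
    # dims as it spreads and J stays constant under deformation
    content = optics.photon_scale * truth.areas[0]

    for t in range(truth.n_frames):
        signal = np.zeros((n_px, n_px))
        for i in range(truth.n_cells):
            amp_px = content[i] / truth.areas[t, i] * px ** 2
            area_px = truth.areas[t, i] / px ** 2
            q = truth.aspect[i]
            # uniform ellipse of the nucleus's area, aspect q
            b = np.sqrt(area_px / (np.pi * q))   # semi-minor, px
            a = q * b
            cx = truth.positions[t, i, 0] / px - 0.5
            cy = truth.positions[t, i, 1] / px - 0.5
            th = truth.thetas[t, i]
            half = int(np.ceil(a + 4 * s_psf)) + 1
            jx = np.arange(int(np.floor(cx)) - half, int(np.floor(cx)) + half + 1)
            jy = np.arange(int(np.floor(cy)) - half, int(np.floor(cy)) + half + 1)
            LX, LY = np.meshgrid(jx - cx, jy - cy)
            c, s = np.cos(th), np.sin(th)
            u = c * LX + s * LY
            w = -s * LX + c * LY
            # PSF-smoothed edge: erf profile of the signed distance to the
            # ellipse boundary along the ray (exact for a straight edge)
            rho = np.sqrt((u / a) ** 2 + (w / b) ** 2)
            r = np.hypot(u, w)
            r_edge = np.where(rho > 1e-9, r / np.clip(rho, 1e-9, None), a)
            dist = r_edge - r                      # >0 inside
            spot = amp_px * ndtr(dist / s_psf)
            np.add.at(signal, (np.ix_(jy % n_px, jx % n_px)), spot)
        expected = (signal + optics.background_level) * illum
        noisy = rng.poisson(expected).astype(float)
        noisy += rng.normal(0, optics.read_noise_sigma, noisy.shape)
        frames[t] = np.clip(np.round(noisy), 0, max_val).astype(np.uint16)

    return FrameStack(frames, pixel_size=px, dt=cfg.dt)


# ---------------------------------------------------------------------------
# stretch experiment
# ---------------------------------------------------------------------------


def simulate_stretch_experiment(R: float, beta: float, eps_tot: float,
                                n_fov: int = 30, noise_sd: float = 0.0,
                                seed: int = 0) -> pd.DataFrame:
    """Per-FOV fractional nuclear-area changes under biaxial stretch.

    Forward model of the iso-stress composite: Δa = ε_tot / (β + (1−β)R),
    plus Gaussian measurement noise of sd ``noise_sd`` per field of view.
    """
    if R <= 0 or not 0 < beta < 1 or eps_tot <= 0:
        raise ValueError("require R > 0, beta in (0,1), eps_tot > 0")
    rng = np.random.default_rng(seed)
    da = eps_tot / (beta + (1 - beta) * R)
    vals = da + rng.normal(0, noise_sd, n_fov)
    return pd.DataFrame({"fov": np.arange(n_fov), "delta_a": vals,
                         "beta": np.full(n_fov, beta)})


# ---------------------------------------------------------------------------
# organoid
# ---------------------------------------------------------------------------


def _rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def simulate_organoid(n_cells: int = 60, radius: float = 50.0,
                      omega: np.ndarray | tuple = (0.0, 0.0, 0.04),
                      residual_D: float = 0.0, dt: float = 15.0,
                      n_frames: int = 40, seed: int = 0,
                      ) -> tuple[pd.DataFrame, np.ndarray]:
    """Rigidly rotating organoid nuclear point cloud with Brownian residuals.

    ``omega`` is the angular velocity vector in cycles/h; ``residual_D`` is
    the internal-rearrangement diffusivity in μm²/h; ``dt`` in minutes.
    Returns (per-frame centroid table, true omega vector).
    """
    if n_cells < 4:
        raise ValueError("need >= 4 cells for a non-degenerate rigid fit")
    rng = np.random.default_rng(seed)
    omega = np.asarray(omega, float)

    # uniform-ish points in a ball
    pts = rng.normal(size=(n_cells, 3))
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    pts *= radius * rng.uniform(0.2, 1.0, (n_cells, 1)) ** (1 / 3)

    dt_h = dt / 60.0
    speed = np.linalg.norm(omega)
    rows = []
    body = pts.copy()
    for t in range(n_frames):
        if speed > 0:
            Rm = _rotation_matrix(omega, 2 * np.pi * speed * t * dt_h)
        else:
            Rm = np.eye(3)
        lab = body @ Rm.T
        for i in range(n_cells):
            rows.append((t, i, *lab[i]))
        if residual_D > 0:
            body = body + rng.normal(0, np.sqrt(2 * residual_D * dt_h),
                                     (n_cells, 3))
    df = pd.DataFrame(rows, columns=["frame", "cell_id", "x_um", "y_um", "z_um"])
    return df, omega


# ---------------------------------------------------------------------------
# tracers
# ---------------------------------------------------------------------------


def simulate_tracer_walk(D: float, n_tracks: int = 200, dt: float = 0.02,
                         n_steps: int = 500, seed: int = 0) -> pd.DataFrame:
    """2-D Brownian tracer trajectories (increment variance 2·D·dt per axis).

    ``D`` in μm²/s, ``dt`` in seconds.  Returns a (track_id, frame, x_um,
    y_um) table.
    """
    rng = np.random.default_rng(seed)
    steps = rng.normal(0, np.sqrt(2 * D * dt) if D > 0 else 0.0,
                       (n_tracks, n_steps, 2))
    xy = np.concatenate([np.zeros((n_tracks, 1, 2)), np.cumsum(steps, axis=1)],
                        axis=1)
    t, n = np.meshgrid(np.arange(n_steps + 1), np.arange(n_tracks))
    return pd.DataFrame({"track_id": n.ravel(), "frame": t.ravel(),
                         "x_um": xy[..., 0].ravel(), "y_um": xy[..., 1].ravel()})


# ---------------------------------------------------------------------------
# planted-correlation velocity sample (for C_vv validation)
# ---------------------------------------------------------------------------


def correlated_velocity_sample(n_points: int, box: float, corr_length: float,
                               seed: int = 0, n_modes: int = 512,
                               ) -> tuple[np.ndarray, np.ndarray]:
    """Scattered unit-speed velocities whose directional correlation is
    exponential: ⟨cos(θ_i − θ_j)⟩ = e^(−r/L) with L = ``corr_length``.

    The headings form a Gaussian random surface with a *linear variogram*
    γ(r) = 2r/L (fractional-Brownian-type, synthesised from log-uniformly
    sampled Fourier modes with k⁻³ spectrum), for which the circular
    statistics identity ⟨cos Δθ⟩ = e^(−γ(r)/2) makes the planted
    correlation exact over the resolved scale range.  Returns (positions
    (n, 2), unit velocities (n, 2)).
    """
    from scipy.special import j0

    rng = np.random.default_rng(seed)
    pos = rng.uniform(0, box, (n_points, 2))
    kmin = 2 * np.pi / (40.0 * box)
    kmax = 2 * np.pi / (corr_length / 50.0)
    u = rng.uniform(size=n_modes)
    kmag = kmin * (kmax / kmin) ** u            # log-uniform
    ang = rng.uniform(0, 2 * np.pi, n_modes)
    phase = rng.uniform(0, 2 * np.pi, n_modes)
    amp2 = 1.0 / kmag                            # k⁻³ spectrum × importance k
    # calibrate: gamma(r) = 2 Σ a² (1 − J0(k r)) must equal 2 r / L at r = L
    gamma_ref = 2.0 * np.sum(amp2 * (1 - j0(kmag * corr_length)))
    amp2 *= (2.0 * corr_length / corr_length) / gamma_ref  # target 2·(r/L)=2
    amp = np.sqrt(2.0 * amp2)
    kx = kmag * np.cos(ang)
    ky = kmag * np.sin(ang)
    theta = (amp[None, :] * np.cos(pos[:, 0][:, None] * kx[None, :]
                                   + pos[:, 1][:, None] * ky[None, :]
                                   + phase[None, :])).sum(axis=1)
    return pos, np.column_stack([np.cos(theta), np.sin(theta)])
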