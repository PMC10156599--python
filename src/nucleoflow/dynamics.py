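"""Collective-motility statistics and nuclear strain dynamics.

Implements the kinematic observables of monolayer unjamming — the mean
migration velocity v_cm, the velocity fluctuation amplitude v_rms in the
centre-of-mass frame, the spatial velocity correlation C_vv(r) with its
stretched-exponential correlation length L_c — and the nuclear strain
dynamics: the mean square strain MSS(τ) of normalised nuclear-area changes
with its three-parameter model fit, the instantaneous nuclear strain rate
γ̇_N = (1/A)∂A/∂t, and a two-segment wound-closure velocity fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .segtrack import TrackSet

__all__ = [
    "MotilitySummary",
    "StrainCurve",
    "motility_stats",
    "velocity_correlation",
    "fit_correlation_length",
    "mss_curve",
    "fit_mss",
    "mss_gamma0_uncertainty",
    "nuclear_strain_rate",
    "track_velocities",
    "wound_closure_velocity",
]


@dataclass
class MotilitySummary:
    """Per-frame collective-motility observables (μm/min)."""

    frames: np.ndarray
    v_cm: np.ndarray          # (T, 2)
    v_rms: np.ndarray         # (T,)

    @property
    def mean_polarisation(self) -> float:
        """Time-averaged |v_cm| / v_rms — order parameter of flocking."""
        vrms = np.where(self.v_rms > 0, self.v_rms, np.nan)
        return float(np.nanmean(np.hypot(*self.v_cm.T) / vrms))


@dataclass
class StrainCurve:
    """MSS(τ) curve (τ in hours, MSS dimensionless) and its model fit."""

    tau: np.ndarray
    mss: np.ndarray
    sigma_w: float = np.nan
    gamma0: float = np.nan    # h⁻¹
    tau_c: float = np.nan     # h
    cov: np.ndarray | None = None

    @property
    def baseline_subtracted(self) -> np.ndarray:
        return self.mss - self.sigma_w


# ---------------------------------------------------------------------------
# velocities
# ---------------------------------------------------------------------------


def track_velocities(tracks: TrackSet, use_filter: bool = True) -> pd.DataFrame:
    """Central-difference instantaneous velocities per (track, frame).

    v_i(t) = (x_i(t+1) − x_i(t−1)) / (2 δt) in μm/min, computed only where
    both neighbouring frames are present (and unflagged when ``use_filter``).
    """
    df = tracks.usable() if use_filter else tracks.df
    out = []
    for tid, grp in df.groupby("track_id"):
        fr = grp["frame"].to_numpy()
        x = grp["x_um"].to_numpy(float)
        y = grp["y_um"].to_numpy(float)
        if len(fr) < 3:
            continue
        # consecutive-frame triplets only
        ok = (fr[2:] - fr[:-2]) == 2
        vx = (x[2:] - x[:-2]) / (2 * tracks.dt)
        vy = (y[2:] - y[:-2]) / (2 * tracks.dt)
        for i in np.flatnonzero(ok):
            out.append((tid, fr[i + 1], x[i + 1], y[i + 1], vx[i], vy[i]))
    return pd.DataFrame(out, columns=["track_id", "frame", "x_um", "y_um",
                                      "vx", "vy"])


def motility_stats(tracks: TrackSet, window: tuple[float, float] | None = None,
                   ) -> MotilitySummary:
    """v_cm(t) over all nuclei in the FOV and v_rms(t) in the v_cm frame.

    ``window`` restricts the analysis to a time interval in hours.
    """
    vel = track_velocities(tracks)
    if window is not None:
        t_h = vel["frame"] * tracks.dt / 60.0
        vel = vel[(t_h >= window[0]) & (t_h <= window[1])]
    if vel.empty:
        raise ValueError("no velocities available (tracks too short?)")
    frames, vcm, vrms = [], [], []
    for fr, grp in vel.groupby("frame"):
        v = grp[["vx", "vy"]].to_numpy(float)
        cm = v.mean(axis=0)
        frames.append(fr)
        vcm.append(cm)
        vrms.append(np.sqrt(np.mean(((v - cm) ** 2).sum(axis=1))))
    return MotilitySummary(np.array(frames), np.array(vcm), np.array(vrms))


# ---------------------------------------------------------------------------
# velocity correlation
# ---------------------------------------------------------------------------


def velocity_correlation(tracks_or_sample, bin_width: float = 14.0,
                         r_max: float | None = None,
                         window: tuple[float, float] | None = None,
                         subtract_cm: bool = False,
                         ) -> pd.DataFrame:
    """Radial velocity direction correlation C_vv(r).

    C_vv(r) is the time- and pair-average of cos of the angle between the
    velocities of nuclei separated by r (lab frame by default; set
    ``subtract_cm`` for drift-dominated data).  Input is either a TrackSet or
    a (positions, velocities) tuple for a single snapshot.  Returns a table
    (r_um, cvv, n_pairs).
    """
    if isinstance(tracks_or_sample, TrackSet):
        tracks = tracks_or_sample
        vel = track_velocities(tracks)
        if window is not None:
            t_h = vel["frame"] * tracks.dt / 60.0
            vel = vel[(t_h >= window[0]) & (t_h <= window[1])]
        snapshots = [
            (g[["x_um", "y_um"]].to_numpy(float), g[["vx", "vy"]].to_numpy(float))
            for _, g in vel.groupby("frame")
        ]
    else:
        snapshots = [tracks_or_sample]

    sums: dict[int, float] = {}
    counts: dict[int, int] = {}
    for pos, v in snapshots:
        if len(pos) < 2:
            continue
        if subtract_cm:
            v = v - v.mean(axis=0)
        norm = np.linalg.norm(v, axis=1)
        ok = norm > 0
        pos, v, norm = pos[ok], v[ok], norm[ok]
        n = len(pos)
        if n < 2:
            continue
        iu = np.triu_indices(n, 1)
        dr = np.hypot(pos[iu[0], 0] - pos[iu[1], 0],
                      pos[iu[0], 1] - pos[iu[1], 1])
        cosang = (v[iu[0]] * v[iu[1]]).sum(axis=1) / (norm[iu[0]] * norm[iu[1]])
        if r_max is not None:
            keep = dr <= r_max
            dr, cosang = dr[keep], cosang[keep]
        b = (dr // bin_width).astype(int)
        for bi in np.unique(b):
            m = b == bi
            sums[bi] = sums.get(bi, 0.0) + cosang[m].sum()
            counts[bi] = counts.get(bi, 0) + int(m.sum())
    bins = sorted(counts)
    return pd.DataFrame({
        "r_um": [(b + 0.5) * bin_width for b in bins],
        "cvv": [sums[b] / counts[b] for b in bins],
        "n_pairs": [counts[b] for b in bins],
    })


def fit_correlation_length(cvv: pd.DataFrame,
                           ) -> tuple[float, float, np.ndarray]:
    """Fit C_vv(r) = exp(−(r/L_c)^α); returns (L_c, α, covariance).

    Weighted least squares with pair-count weights over r > 0 bins;
    α is bounded to (0.2, 3].
    """
    r = cvv["r_um"].to_numpy(float)
    c = cvv["cvv"].to_numpy(float)
    w = cvv["n_pairs"].to_numpy(float)
    keep = r > 0
    r, c, w = r[keep], c[keep], w[keep]
    if len(r) < 4:
        raise ValueError("fewer than 4 populated bins; cannot fit L_c")

    def model(r, lc, alpha):
        return np.exp(-((r / lc) ** alpha))

    # crude init: radius where C drops below 1/e
    below = np.nonzero(c < np.exp(-1))[0]
    lc0 = r[below[0]] if len(below) else r[-1] / 2
    popt, pcov = curve_fit(model, r, c, p0=[lc0, 1.0],
                           sigma=1.0 / np.sqrt(w), absolute_sigma=False,
                           bounds=([1e-6, 0.2], [np.inf, 3.0]), maxfev=10000)
    return float(popt[0]), float(popt[1]), pcov


# ---------------------------------------------------------------------------
# mean square nuclear strain
# ---------------------------------------------------------------------------


def _track_area_series(tracks: TrackSet, min_length: int,
                       ) -> list[tuple[int, np.ndarray, np.ndarray]]:
    """(track_id, frames, areas) per usable track, flagged frames removed."""
    out = []
    for tid, grp in tracks.usable().groupby("track_id"):
        fr = grp["frame"].to_numpy()
        a = grp["area_um2"].to_numpy(float)
        if len(fr) >= max(2, min_length):
            out.append((tid, fr, a))
    return out


def mss_curve(tracks: TrackSet, tau_grid_frames: np.ndarray | None = None,
              max_tau_fraction: float = 1 / 3, min_track_length: int = 10,
              track_subset: np.ndarray | None = None) -> StrainCurve:
    """Mean square nuclear strain MSS(τ).

    Δa_i(τ|t) = [A_i(t+τ) − A_i(t)] / ⟨A_i⟩_t; MSS(τ) averages Δa² over t
    within each track, then over tracks.  Flagged frames are excluded
    pairwise, and only tracks with at least ``min_track_length`` usable
    frames contribute — transient mis-segmentations form short spurious
    tracks whose squared strains would otherwise dominate the small-τ
    average.  The default τ grid spans integer frame lags up to
    ``max_tau_fraction`` of the observation span.
    """
    series = _track_area_series(tracks, min_track_length)
    if track_subset is not None:
        wanted = set(np.asarray(track_subset).tolist())
        series = [s for s in series if s[0] in wanted]
    series = [(fr, a) for _, fr, a in series]
    if not series:
        raise ValueError("no usable tracks")
    span = max(fr.max() for fr, _ in series) - min(fr.min() for fr, _ in series)
    if tau_grid_frames is None:
        tau_grid_frames = np.arange(1, max(2, int(span * max_tau_fraction)) + 1)

    mss = np.full(len(tau_grid_frames), np.nan)
    for k, tau in enumerate(tau_grid_frames):
        per_track = []
        for fr, a in series:
            mean_a = a.mean()
            idx = {f: i for i, f in enumerate(fr)}
            d2 = [((a[idx[f + tau]] - a[i]) / mean_a) ** 2
                  for i, f in enumerate(fr) if f + tau in idx]
            if d2:
                per_track.append(np.mean(d2))
        if per_track:
            mss[k] = np.mean(per_track)
    keep = ~np.isnan(mss)
    tau_h = tau_grid_frames[keep] * tracks.dt / 60.0
    return StrainCurve(tau_h, mss[keep])


def fit_mss(curve: StrainCurve) -> StrainCurve:
    """Fit MSS(τ) = σ_w + γ̇₀ τ_c (1 − e^(−τ/τ_c)).

    σ_w absorbs white measurement noise in the area determination; γ̇₀ is
    the short-time strain rate (the robust parameter), γ̇₀τ_c the plateau.
    Initialisation: σ_w = MSS(τ_min), γ̇₀ = initial slope, τ_c = span/4.
    The fit is weighted relatively (σ ∝ MSS) so the accurately sampled
    short-τ regime, which determines γ̇₀, is not swamped by the many
    plateau points.
    """
    tau, mss = curve.tau, curve.mss
    if len(tau) < 4:
        raise ValueError("need >= 4 tau points to fit the MSS model")

    def model(t, sw, g0, tc):
        return sw + g0 * tc * (1 - np.exp(-t / tc))

    sw0 = max(mss[0], 1e-12)
    slope0 = max((mss[min(2, len(mss) - 1)] - mss[0])
                 / (tau[min(2, len(tau) - 1)] - tau[0] + 1e-12), 1e-9)
    p0 = [sw0, slope0, max(tau[-1] / 4, tau[0])]
    weights = np.clip(mss, max(1e-12, 1e-3 * np.nanmax(mss)), None)
    try:
        popt, pcov = curve_fit(model, tau, mss, p0=p0, sigma=weights,
                               bounds=([0, 0, 1e-6], [np.inf] * 3),
                               maxfev=20000)
    except RuntimeError as e:
        raise RuntimeError(f"MSS fit failed to converge: {e}") from e
    return StrainCurve(tau, mss, float(popt[0]), float(popt[1]),
                       float(popt[2]), pcov)


def mss_gamma0_uncertainty(tracks: TrackSet, n_subsets: int = 10,
                           subset_fraction: float = 0.5, seed: int = 0,
                           **mss_kw) -> tuple[float, float]:
    """γ̇₀ mean ± sd over ``n_subsets`` random track subsets."""
    rng = np.random.default_rng(seed)
    ids = tracks.usable()["track_id"].unique()
    vals = []
    for _ in range(n_subsets):
        sub = rng.choice(ids, size=max(2, int(len(ids) * subset_fraction)),
                         replace=False)
        sub_df = tracks.df[tracks.df["track_id"].isin(sub)]
        sub_tracks = TrackSet(sub_df.copy(), tracks.pixel_size, tracks.dt,
                              tracks.excluded)
        vals.append(fit_mss(mss_curve(sub_tracks, **mss_kw)).gamma0)
    return float(np.mean(vals)), float(np.std(vals))


# ---------------------------------------------------------------------------
# nuclear strain rate
# ---------------------------------------------------------------------------


def nuclear_strain_rate(frames: np.ndarray, areas: np.ndarray, dt: float,
                        ) -> np.ndarray:
    """Instantaneous nuclear strain rate γ̇_N = (1/A) ∂A/∂t (min⁻¹).

    Central differences in the interior, one-sided at the ends; entries with
    missing neighbouring frames are NaN.
    """
    frames = np.asarray(frames)
    a = np.asarray(areas, float)
    n = len(a)
    out = np.full(n, np.nan)
    if n < 2:
        return out
    for i in range(n):
        if 0 < i < n - 1 and frames[i + 1] - frames[i - 1] == 2:
            out[i] = (a[i + 1] - a[i - 1]) / (2 * dt) / a[i]
        elif i == 0 and frames[1] - frames[0] == 1:
            out[i] = (a[1] - a[0]) / dt / a[0]
        elif i == n - 1 and frames[-1] - frames[-2] == 1:
            out[i] = (a[-1] - a[-2]) / dt / a[-1]
    return out


# ---------------------------------------------------------------------------
# wound closure
# ---------------------------------------------------------------------------


def wound_closure_velocity(t: np.ndarray, covered_area: np.ndarray,
                           ) -> tuple[float, float]:
    """Two-straight-line fit of covered area vs time.

    Continuous piecewise-linear least squares with the breakpoint chosen by
    exhaustive scan over interior samples; returns (breakpoint time,
    second-segment slope = maximal closure velocity).
    """
    t = np.asarray(t, float)
    y = np.asarray(covered_area, float)
    if len(t) < 6:
        raise ValueError("need >= 6 time points")
    best = (np.inf, t[1], 0.0)
    for kb in range(1, len(t) - 1):
        tb = t[kb]
        X = np.column_stack([np.ones_like(t), t - tb,
                             np.clip(t - tb, 0, None)])
        coef, res, *_ = np.linalg.lstsq(X, y, rcond=None)
        pred = X @ coef
        sse = float(((y - pred) ** 2).sum())
        if sse < best[0] - 1e-12:
            best = (sse, tb, float(coef[1] + coef[2]))
    return best[1], best[2]
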