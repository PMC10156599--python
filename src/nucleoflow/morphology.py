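"""Nuclear and cell shape statistics, intensity readouts and tracer MSD.

Excess of perimeter (EOP) of nuclear contours, rigid registration and
line-scan localisation of nuclear-envelope fluctuations, robust aspect-ratio
deformation rate in constricted channels, boundary deformation (MPD/MND)
between consecutive cell outlines, nuclear foci counting, central/peripheral
intensity partitioning, and tracer mean-square displacement with apparent
diffusivity.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.optimize import minimize_scalar
from shapely.geometry import Point, Polygon
from skimage.morphology import reconstruction
from skimage.registration import phase_cross_correlation
from skimage.transform import rotate
import statsmodels.api as sm

__all__ = [
    "excess_of_perimeter",
    "register_rigid",
    "envelope_fluctuations",
    "aspect_ratio_rate",
    "boundary_deformation",
    "count_foci",
    "central_peripheral_ratio",
    "msd_and_diffusion",
]


# ---------------------------------------------------------------------------
# excess of perimeter
# ---------------------------------------------------------------------------


def excess_of_perimeter(boundary: np.ndarray) -> float:
    """EOP = (P − 2πR₀)/(2πR₀) with R₀ = √(A/π) the equal-area circle radius.

    Zero for a circle; approaches 1 for deeply folded (floppy) contours.
    ``boundary`` is a closed simple polygon, (n, 2) in μm.
    """
    poly = Polygon(np.asarray(boundary, float))
    if not poly.is_valid:
        raise ValueError("boundary polygon is self-intersecting or degenerate")
    p = poly.exterior.length
    r0 = np.sqrt(poly.area / np.pi)
    circ = 2 * np.pi * r0
    return float((p - circ) / circ)


# ---------------------------------------------------------------------------
# rigid registration
# ---------------------------------------------------------------------------


def register_rigid(stack: np.ndarray, angle_range: float = 10.0,
                   upsample: int = 20,
                   ) -> tuple[np.ndarray, pd.DataFrame]:
    """Align each frame to the first by rotation + translation.

    For each frame the rotation angle (within ±``angle_range`` degrees) is
    optimised so that the phase-correlation against the reference peaks;
    the remaining shift is then removed at sub-pixel precision.  Returns the
    aligned stack and a table (frame, shift_y, shift_x, angle_deg).
    """
    stack = np.asarray(stack, float)
    if stack.ndim == 2:
        stack = stack[None]
    ref = stack[0]
    out = np.empty_like(stack)
    out[0] = ref
    rows = [(0, 0.0, 0.0, 0.0)]

    ref_zm = ref - ref.mean()
    ref_f = np.conj(np.fft.rfft2(ref_zm))

    def peak_height(frame):
        fz = frame - frame.mean()
        sd = fz.std()
        if sd == 0:
            return 0.0
        c = np.fft.irfft2(ref_f * np.fft.rfft2(fz), s=ref.shape)
        return float(c.max() / (sd * ref_zm.std() * ref.size + 1e-300))

    for t in range(1, len(stack)):
        frame = stack[t]
        if angle_range > 0:
            res = minimize_scalar(
                lambda ang: -peak_height(rotate(frame, ang, preserve_range=True,
                                                mode="edge")),
                bounds=(-angle_range, angle_range), method="bounded",
                options={"xatol": 0.005})
            ang = float(res.x)
        else:
            ang = 0.0
        rot = rotate(frame, ang, preserve_range=True, mode="edge")
        shift, _, _ = phase_cross_correlation(ref, rot,
                                              upsample_factor=upsample)
        out[t] = ndi.shift(rot, shift, mode="nearest")
        rows.append((t, float(shift[0]), float(shift[1]), ang))
    return out, pd.DataFrame(rows, columns=["frame", "shift_y", "shift_x",
                                            "angle_deg"])


# ---------------------------------------------------------------------------
# nuclear-envelope fluctuations
# ---------------------------------------------------------------------------


def _edge_position(profile: np.ndarray) -> float:
    """Sub-pixel edge along a 1-D profile: |gradient| maximum with 3-point
    parabolic refinement; NaN when the profile is flat."""
    g = np.abs(np.gradient(profile.astype(float)))
    if g.max() == 0:
        return np.nan
    i = int(np.argmax(g))
    if 0 < i < len(g) - 1:
        denom = g[i - 1] - 2 * g[i] + g[i + 1]
        if denom != 0:
            return i + 0.5 * (g[i - 1] - g[i + 1]) / denom
    return float(i)


def envelope_fluctuations(stack: np.ndarray, center: tuple[float, float],
                          n_scans: int = 8, scan_length: float | None = None,
                          pixel_size: float = 1.0) -> np.ndarray:
    """Per-scan standard deviation of the nuclear-envelope position (μm).

    ``n_scans`` radial line scans at equal angles are drawn from ``center``
    (x, y in px) across the envelope of a registered single-nucleus stack;
    per frame the envelope is localised on each scan at the intensity-
    gradient maximum (sub-pixel), and the sd of that position over time is
    one measure per scan point.
    """
    stack = np.asarray(stack, float)
    if stack.ndim == 2:
        stack = stack[None]
    h, w = stack.shape[1:]
    if scan_length is None:
        scan_length = 0.48 * min(h, w)
    cx, cy = center
    angles = np.arange(n_scans) * (2 * np.pi / n_scans)
    n_samp = int(2 * scan_length)
    s = np.linspace(0, scan_length, n_samp)
    positions = np.full((len(stack), n_scans), np.nan)
    for t, frame in enumerate(stack):
        for a, ang in enumerate(angles):
            xs = cx + s * np.cos(ang)
            ys = cy + s * np.sin(ang)
            prof = ndi.map_coordinates(frame, np.vstack([ys, xs]), order=1,
                                       mode="nearest")
            e = _edge_position(prof)
            if np.isfinite(e):
                positions[t, a] = e * (s[1] - s[0])
    return np.nanstd(positions, axis=0) * pixel_size


# ---------------------------------------------------------------------------
# aspect-ratio deformation rate
# ---------------------------------------------------------------------------


def aspect_ratio_rate(t: np.ndarray, ar: np.ndarray) -> float:
    """Robust (bisquare M-estimator) slope of aspect ratio vs time (s⁻¹).

    Tolerates a minority of gross outliers, as expected from transient
    segmentation failures while a nucleus squeezes through a constriction.
    """
    t = np.asarray(t, float)
    ar = np.asarray(ar, float)
    X = sm.add_constant(t)
    fit = sm.RLM(ar, X, M=sm.robust.norms.TukeyBiweight(c=4.685)).fit()
    return float(fit.params[1])


# ---------------------------------------------------------------------------
# boundary deformation
# ---------------------------------------------------------------------------


def boundary_deformation(poly_t: np.ndarray, poly_t1: np.ndarray,
                         ) -> tuple[float, float]:
    """Maximum positive / negative boundary deformation (MPD, MND).

    For each vertex of the later outline ``poly_t1``, the minimum distance to
    the earlier outline ``poly_t`` is signed by containment: outside the
    earlier shape = positive (protrusion into new territory), inside =
    negative (retraction).  Returns (MPD, MND), both ≥ 0.
    """
    earlier = Polygon(np.asarray(poly_t, float))
    if not earlier.is_valid:
        raise ValueError("earlier polygon is invalid")
    ring = earlier.exterior
    mpd = 0.0
    mnd = 0.0
    for x, y in np.asarray(poly_t1, float):
        pt = Point(x, y)
        d = ring.distance(pt)
        if earlier.contains(pt):
            mnd = max(mnd, d)
        else:
            mpd = max(mpd, d)
    return mpd, mnd


# ---------------------------------------------------------------------------
# foci and intensity partition
# ---------------------------------------------------------------------------


def count_foci(roi_mask: np.ndarray, foci_image: np.ndarray,
               noise_tolerance: float) -> int:
    """Count intensity maxima of prominence > ``noise_tolerance`` in the ROI.

    H-maxima transform: peaks that do not stand out from their surroundings
    by more than the tolerance are suppressed, remaining maxima regions are
    counted within the nucleus mask.  The tolerance is an explicit
    experiment-specific setting, never auto-tuned.
    """
    img = np.asarray(foci_image, float)
    mask = np.asarray(roi_mask, bool)
    if noise_tolerance <= 0:
        raise ValueError("noise_tolerance must be positive")
    if np.ptp(img[mask]) <= noise_tolerance:
        return 0
    seed = img - noise_tolerance
    rec = reconstruction(seed, img, method="dilation")
    hmax = img - rec > (noise_tolerance / 2.0)
    lab, n = ndi.label(hmax & mask)
    return int(n)


def central_peripheral_ratio(roi_mask: np.ndarray, image: np.ndarray,
                             shrink_um: float = 1.5,
                             pixel_size: float = 1.0) -> float:
    """Mean intensity of the nuclear core over the peripheral rim.

    The core is the ROI eroded by ``shrink_um`` from the border; the rim is
    the remainder of the ROI.  Raises if the erosion eliminates the core.
    """
    mask = np.asarray(roi_mask, bool)
    img = np.asarray(image, float)
    n_iter = int(round(shrink_um / pixel_size))
    core = ndi.binary_erosion(mask, iterations=max(1, n_iter))
    if not core.any():
        raise ValueError("shrink eliminates the central region")
    rim = mask & ~core
    if not rim.any():
        raise ValueError("ROI thinner than the shrink distance")
    return float(img[core].mean() / img[rim].mean())


# ---------------------------------------------------------------------------
# tracer MSD
# ---------------------------------------------------------------------------


def msd_and_diffusion(tracks: pd.DataFrame, dt: float,
                      fit_fraction: float = 0.25,
                      ) -> tuple[pd.DataFrame, float, bool]:
    """Ensemble time-averaged MSD and the apparent diffusion coefficient.

    ``tracks``: (track_id, frame, x_um, y_um); ``dt`` frame interval in the
    time unit of the desired D (s for μm²/s).  D_app is the slope/4 of the
    through-origin linear fit of MSD(τ) over the first ``fit_fraction`` of
    lags; a curvature diagnostic flags non-diffusive (e.g. ballistic) data.
    Returns (msd table with columns tau, msd, n; D_app; linear_ok).
    """
    per_lag_sum: dict[int, float] = {}
    per_lag_n: dict[int, int] = {}
    for _, grp in tracks.groupby("track_id"):
        grp = grp.sort_values("frame")
        xy = grp[["x_um", "y_um"]].to_numpy(float)
        n = len(xy)
        for lag in range(1, n):
            d = xy[lag:] - xy[:-lag]
            per_lag_sum[lag] = per_lag_sum.get(lag, 0.0) + float(
                (d ** 2).sum())
            per_lag_n[lag] = per_lag_n.get(lag, 0) + len(d)
    lags = np.array(sorted(per_lag_sum))
    msd = np.array([per_lag_sum[l] / per_lag_n[l] for l in lags])
    tab = pd.DataFrame({"tau": lags * dt, "msd": msd,
                        "n": [per_lag_n[l] for l in lags]})

    k = max(2, int(len(lags) * fit_fraction))
    tau_fit = tab["tau"].to_numpy()[:k]
    msd_fit = tab["msd"].to_numpy()[:k]
    denom = np.sum(tau_fit ** 2)
    slope = float(np.sum(tau_fit * msd_fit) / denom) if denom > 0 else 0.0
    d_app = slope / 4.0

    # curvature diagnostic: quadratic term relative to linear prediction
    linear_ok = True
    if len(tau_fit) >= 3 and msd_fit.max() > 0:
        quad = np.polyfit(tau_fit, msd_fit, 2)
        curv = abs(quad[0]) * tau_fit[-1] ** 2
        linear_ok = bool(curv < 0.25 * max(msd_fit[-1], 1e-300))
    return tab, d_app, linear_ok
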