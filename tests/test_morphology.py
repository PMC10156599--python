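"""Shape metrics, registration, envelope fluctuations, foci and MSD."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import ndimage as ndi
from skimage.transform import rotate

from nucleoflow import morphology, synthetic


def ellipse_polygon(a, b, n=512, rot=0.0, centre=(0.0, 0.0)):
    t = np.linspace(0, 2 * np.pi, n + 1)[:-1]
    x = a * np.cos(t)
    y = b * np.sin(t)
    c, s = np.cos(rot), np.sin(rot)
    return np.column_stack([c * x - s * y + centre[0],
                            s * x + c * y + centre[1]])


class TestEOP:
    def test_circle_is_zero(self):
        assert morphology.excess_of_perimeter(
            ellipse_polygon(10, 10, 256)) == pytest.approx(0.0, abs=1e-4)

    def test_two_to_one_ellipse(self):
        # oracle: numerical arc length quadrature vs equal-area circle
        poly = ellipse_polygon(2.0, 1.0, 4096)
        seg = np.diff(np.vstack([poly, poly[:1]]), axis=0)
        perim = np.hypot(seg[:, 0], seg[:, 1]).sum()
        r0 = np.sqrt(2.0 * 1.0)            # area = pi*a*b
        oracle = (perim - 2 * np.pi * r0) / (2 * np.pi * r0)
        assert oracle == pytest.approx(0.0903, abs=2e-3)
        assert morphology.excess_of_perimeter(poly) == pytest.approx(
            oracle, abs=1e-4)

    def test_folded_star_approaches_one(self):
        t = np.linspace(0, 2 * np.pi, 4001)[:-1]
        r = 10 + 4.5 * np.sin(24 * t)
        poly = np.column_stack([r * np.cos(t), r * np.sin(t)])
        assert morphology.excess_of_perimeter(poly) > 0.6

    def test_similarity_invariance(self):
        base = ellipse_polygon(3, 1.5, 1024)
        ref = morphology.excess_of_perimeter(base)
        for rot, scale, shift in [(0.7, 2.0, (5, -3)), (2.2, 0.3, (0, 9))]:
            poly = ellipse_polygon(3 * scale, 1.5 * scale, 1024, rot=rot,
                                   centre=shift)
            assert morphology.excess_of_perimeter(poly) == pytest.approx(
                ref, rel=1e-6)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(a=st.floats(1.0, 6.0), b=st.floats(1.0, 6.0),
           rot=st.floats(0, 2 * np.pi), scale=st.floats(0.1, 10.0),
           dx=st.floats(-50, 50), dy=st.floats(-50, 50))
    def test_similarity_invariance_property(self, a, b, rot, scale, dx, dy):
        base = morphology.excess_of_perimeter(ellipse_polygon(a, b, 512))
        moved = morphology.excess_of_perimeter(
            ellipse_polygon(a * scale, b * scale, 512, rot=rot,
                            centre=(dx, dy)))
        assert moved == pytest.approx(base, rel=1e-9, abs=1e-12)

    def test_self_intersection_rejected(self):
        bowtie = np.array([[0, 0], [2, 2], [2, 0], [0, 2.0]])
        with pytest.raises(ValueError):
            morphology.excess_of_perimeter(bowtie)


class TestRegistration:
    @pytest.fixture(scope="class")
    def textured(self):
        rng = np.random.default_rng(1)
        yy, xx = np.mgrid[0:192, 0:192]
        img = ndi.gaussian_filter(
            rng.poisson(200, (192, 192)).astype(float), 1.2)
        img *= np.exp(-(np.hypot(xx - 96, yy - 96) / 70) ** 4)
        return img

    def test_planted_transforms_recovered(self, textured):
        planted = [(3, -2, 1.5), (-2, 3, -2.0), (1, 1, 0.7)]
        stack = [textured]
        for dy, dx, ang in planted:
            fr = ndi.shift(rotate(textured, ang, preserve_range=True,
                                  mode="constant"), (dy, dx),
                           mode="constant")
            stack.append(fr)
        _, tab = morphology.register_rigid(np.array(stack))
        for row, (dy, dx, ang) in zip(tab.iloc[1:].itertuples(), planted):
            assert row.angle_deg == pytest.approx(-ang, abs=0.1)
            # recovered shift equals -(dy,dx) rotated by the found angle
            th = np.radians(row.angle_deg)
            exp = -np.array([[np.cos(th), -np.sin(th)],
                             [np.sin(th), np.cos(th)]]) @ np.array([dy, dx])
            assert row.shift_y == pytest.approx(exp[0], abs=0.1)
            assert row.shift_x == pytest.approx(exp[1], abs=0.1)

    def test_static_stack_identity(self, textured):
        _, tab = morphology.register_rigid(np.array([textured] * 3))
        assert np.abs(tab[["shift_y", "shift_x"]].to_numpy()).max() < 0.05
        assert np.abs(tab["angle_deg"].to_numpy()).max() < 0.05

    def test_single_frame_no_error(self, textured):
        out, tab = morphology.register_rigid(textured)
        assert len(tab) == 1


class TestEnvelope:
    def ring_stack(self, radii, shape=(128, 128)):
        yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
        frames = [ndi.gaussian_filter(
            100.0 * (np.hypot(xx - 64, yy - 64) < r), 1.5) for r in radii]
        return np.array(frames)

    def test_static_ring_zero_sd(self):
        stack = self.ring_stack([30.0] * 10)
        sd = morphology.envelope_fluctuations(stack, center=(64, 64))
        assert sd.max() < 0.05

    def test_oscillating_ring_sinusoid_variance(self):
        t = np.arange(80)
        stack = self.ring_stack(30 + 1.5 * np.sin(2 * np.pi * t / 10))
        sd = morphology.envelope_fluctuations(stack, center=(64, 64))
        assert np.allclose(sd, 1.5 / np.sqrt(2), rtol=0.12)

    def test_sampling_scheme_eight_scans_per_cell(self):
        stack = self.ring_stack([30.0] * 5)
        sds = [morphology.envelope_fluctuations(stack, center=(64, 64),
                                                n_scans=8)
               for _ in range(10)]            # 10 cells
        measures = np.concatenate(sds)
        assert measures.shape == (80,)        # 8 scans × 10 cells


class TestAspectRatioRate:
    def test_exact_line(self):
        t = np.arange(0, 30, 1.0)
        assert morphology.aspect_ratio_rate(t, 1.0 + 0.02 * t) == \
            pytest.approx(0.02, rel=1e-9)

    def test_robust_to_15pct_outliers(self, rng):
        t = np.arange(0, 40, 1.0)
        ar = 1.0 + 0.02 * t
        idx = rng.choice(len(t), size=6, replace=False)
        ar[idx] += rng.uniform(3, 6, size=6)
        assert morphology.aspect_ratio_rate(t, ar) == pytest.approx(
            0.02, rel=0.05)

    def test_constant_ar_zero_slope(self):
        t = np.arange(10.0)
        assert morphology.aspect_ratio_rate(t, np.full(10, 1.4)) == \
            pytest.approx(0.0, abs=1e-12)


def square_polygon(lo, hi, pts_per_edge=25, corners=True):
    s = np.linspace(lo, hi, pts_per_edge + 1)[:-1]
    edges = [np.column_stack([s, np.full_like(s, lo)]),
             np.column_stack([np.full_like(s, hi), s]),
             np.column_stack([s[::-1] + (hi - s[-1]) * 0, np.full_like(s, hi)]),
             np.column_stack([np.full_like(s, lo), s[::-1]])]
    poly = np.vstack(edges)
    if not corners:
        keep = ~(np.isin(poly[:, 0], [lo, hi]) & np.isin(poly[:, 1], [lo, hi]))
        poly = poly[keep]
    return poly


class TestBoundaryDeformation:
    def test_concentric_dilation_uniform_outward_motion(self):
        # boundary moves outward by 1 everywhere -> MPD = 1, MND = 0
        inner = ellipse_polygon(5, 5, 256)
        outer = ellipse_polygon(6, 6, 256)
        mpd, mnd = morphology.boundary_deformation(inner, outer)
        assert mpd == pytest.approx(1.0, abs=1e-3)
        assert mnd == 0.0

    def test_identical_polygons_zero(self):
        sq = square_polygon(0, 10)
        mpd, mnd = morphology.boundary_deformation(sq, sq)
        assert mpd == 0.0 and mnd == 0.0

    def test_translation_oracle(self):
        # point-in-polygon + distance oracle for a unit translation
        sq = square_polygon(0, 10, 50)
        moved = sq + np.array([1.0, 0.0])
        mpd, mnd = morphology.boundary_deformation(sq, moved)
        from shapely.geometry import Point, Polygon
        poly = Polygon(sq)
        pos = neg = 0.0
        for x, y in moved:
            d = poly.exterior.distance(Point(x, y))
            if poly.contains(Point(x, y)):
                neg = max(neg, d)
            else:
                pos = max(pos, d)
        assert mpd == pytest.approx(pos)
        assert mnd == pytest.approx(neg)
        assert mpd == pytest.approx(1.0, abs=1e-9)
        assert mnd == pytest.approx(1.0, abs=1e-9)

    def test_convex_swap_symmetry(self):
        inner = ellipse_polygon(5, 4, 256)
        outer = ellipse_polygon(6.5, 5.5, 256)
        mpd, mnd = morphology.boundary_deformation(inner, outer)
        mpd2, mnd2 = morphology.boundary_deformation(outer, inner)
        assert mpd == pytest.approx(mnd2, abs=1e-2)
        assert mnd == pytest.approx(mpd2, abs=1e-2)


class TestFociAndIntensity:
    def gauss_spots(self, centers, amp, shape=(64, 64), sigma=2.0):
        yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
        img = np.zeros(shape)
        for cy, cx in centers:
            img += amp * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2)
                                / (2 * sigma ** 2))
        return img

    def test_three_spots_counted(self):
        img = self.gauss_spots([(20, 20), (40, 40), (20, 45)], amp=50)
        assert morphology.count_foci(np.ones((64, 64), bool), img, 10.0) == 3

    def test_flat_image_zero(self):
        assert morphology.count_foci(np.ones((64, 64), bool),
                                     np.full((64, 64), 5.0), 10.0) == 0

    def test_spots_below_tolerance_zero(self):
        img = self.gauss_spots([(20, 20), (40, 40)], amp=5)
        assert morphology.count_foci(np.ones((64, 64), bool), img, 10.0) == 0

    def test_uniform_intensity_unit_ratio(self):
        yy, xx = np.mgrid[0:96, 0:96]
        mask = np.hypot(xx - 48, yy - 48) < 30
        img = np.full((96, 96), 4.0)
        assert morphology.central_peripheral_ratio(mask, img, 3.0) == \
            pytest.approx(1.0)

    def test_core_only_signal_large_ratio(self):
        yy, xx = np.mgrid[0:96, 0:96]
        mask = np.hypot(xx - 48, yy - 48) < 30
        img = np.where(np.hypot(xx - 48, yy - 48) < 20, 100.0, 0.01)
        assert morphology.central_peripheral_ratio(mask, img, 5.0) > 10

    def test_radial_gradient_analytic(self):
        yy, xx = np.mgrid[0:160, 0:160]
        r = np.hypot(xx - 80, yy - 80)
        mask = r < 30
        img = np.clip(1.0 - r / 60, 0, None)
        ratio = morphology.central_peripheral_ratio(mask, img, shrink_um=6.0)
        core = 1 - (2 / 3) * 24 / 60
        ring = 1 - (2 / 3) * ((30 ** 3 - 24 ** 3) / (30 ** 2 - 24 ** 2)) / 60
        assert ratio == pytest.approx(core / ring, rel=0.02)

    def test_overshrink_is_error(self):
        yy, xx = np.mgrid[0:32, 0:32]
        mask = np.hypot(xx - 16, yy - 16) < 4
        with pytest.raises(ValueError):
            morphology.central_peripheral_ratio(mask, np.ones((32, 32)), 10.0)


class TestMSD:
    def test_static_tracks(self):
        df = synthetic.simulate_tracer_walk(0.0, n_tracks=5, n_steps=50)
        tab, d, ok = morphology.msd_and_diffusion(df, dt=0.02)
        assert np.allclose(tab["msd"], 0.0)
        assert d == 0.0

    def test_ballistic_flagged_nonlinear(self):
        import pandas as pd
        t = np.arange(200)
        df = pd.DataFrame({"track_id": 0, "frame": t, "x_um": 0.5 * t,
                           "y_um": 0.0})
        tab, d, ok = morphology.msd_and_diffusion(df, dt=1.0)
        assert np.allclose(tab["msd"], (0.5 * tab["tau"]) ** 2)
        assert not ok

    def test_brownian_diffusivity_within_5pct(self):
        df = synthetic.simulate_tracer_walk(0.5, n_tracks=200, dt=0.02,
                                            n_steps=500, seed=3)
        _, d, ok = morphology.msd_and_diffusion(df, dt=0.02)
        assert abs(d - 0.5) / 0.5 < 0.05
        assert ok

    def test_msd_nonnegative_and_zero_at_origin(self):
        df = synthetic.simulate_tracer_walk(0.2, n_tracks=10, n_steps=50,
                                            seed=1)
        tab, _, _ = morphology.msd_and_diffusion(df, dt=1.0)
        assert (tab["msd"] >= 0).all()
        assert tab["tau"].min() > 0   # MSD(0)=0 by construction, not tabulated
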