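"""Segmentation, measurement, linking and quality-filter contracts."""

import itertools

import numpy as np
import pytest
from scipy import ndimage as ndi
from scipy.spatial import cKDTree

import nucleoflow as nf
from nucleoflow import segtrack
from nucleoflow.segtrack import (NucleusObservation, SegmentationConfig,
                                 apply_quality_filter, link_tracks,
                                 measure_nuclei, preprocess, segment_nuclei)


def spot_image(centers, radius=7.0, amp=100.0, shape=(200, 200), edge=1.0):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    img = np.zeros(shape)
    from scipy.special import ndtr
    for cx, cy in centers:
        d = radius - np.hypot(xx - cx, yy - cy)
        img += amp * ndtr(d / edge)
    return img


class TestPreprocess:
    def test_linear_ramp_background_removed(self):
        yy, xx = np.mgrid[0:256, 0:256]
        ramp = 50 + 0.4 * xx
        centers = [(40 + 60 * i, 40 + 60 * j) for i in range(4)
                   for j in range(4)]
        img = spot_image(centers, shape=(256, 256)) + ramp
        out = preprocess(img, SegmentationConfig(nuclear_radius_um=7.0))
        # background residual (far from spots) well below ramp amplitude
        mask = spot_image(centers, radius=14.0, shape=(256, 256)) < 1
        assert np.median(out[mask]) < 0.05 * np.ptp(ramp)

    def test_noiseless_spots_nearly_unchanged(self):
        img = spot_image([(60, 60), (140, 140)])
        out = preprocess(img, SegmentationConfig(nuclear_radius_um=7.0))
        assert np.abs(out - img).max() < 0.02 * img.max() + 1.0

    def test_constant_images_pass_through(self):
        assert np.all(preprocess(np.zeros((64, 64))) == 0)
        assert np.all(preprocess(np.full((64, 64), 7.0)) == 7.0)


class TestSegment:
    def test_well_separated_spots_each_get_one_label(self):
        rng = np.random.default_rng(0)
        centers = [(30 + 45 * i + rng.uniform(-3, 3),
                    30 + 45 * j + rng.uniform(-3, 3))
                   for i in range(5) for j in range(5)]
        img = spot_image(centers, shape=(256, 256))
        img = img + rng.normal(0, 2.0, img.shape)
        cfg = SegmentationConfig(nuclear_radius_um=7.0)
        pre = preprocess(img, cfg)
        labels = segment_nuclei(pre, cfg)
        n = labels.max()
        assert n == len(centers)
        # each label contains exactly one true centre
        owners = set()
        for cx, cy in centers:
            lab = labels[int(round(cy)), int(round(cx))]
            assert lab > 0
            assert lab not in owners
            owners.add(lab)

    def test_blank_frame_gives_no_labels(self):
        labels = segment_nuclei(np.zeros((100, 100)), SegmentationConfig())
        assert labels.max() == 0

    def test_confluent_monolayer_recall_over_90pct(self, flocking_truth,
                                                   rendered_stack):
        cfg = SegmentationConfig()
        pre = preprocess(rendered_stack.data[0], cfg,
                         rendered_stack.pixel_size)
        labels = segment_nuclei(pre, cfg, rendered_stack.pixel_size)
        obs = measure_nuclei(labels, rendered_stack.data[0],
                             rendered_stack.pixel_size, refine_image=pre)
        cents = np.array([[o.x, o.y] for o in obs])
        r_nuc = np.sqrt(flocking_truth.config.mean_nuclear_area / np.pi)
        d, _ = cKDTree(cents).query(flocking_truth.positions[0])
        assert (d < r_nuc).mean() >= 0.90


class TestMeasure:
    def test_rectangle_orientation_and_area(self):
        labels = np.zeros((40, 40), dtype=np.int32)
        labels[10:14, 5:25] = 1          # 20 wide (x) × 4 tall (y)
        img = labels.astype(float)
        obs = measure_nuclei(labels, img, pixel_size=0.5, refine=False)
        assert len(obs) == 1
        assert obs[0].theta == pytest.approx(0.0, abs=1e-6)
        assert obs[0].area == pytest.approx(80 * 0.25)

    def test_rotated_rectangle_orientation(self):
        labels = np.zeros((40, 40), dtype=np.int32)
        labels[5:25, 10:14] = 1          # long axis along y
        obs = measure_nuclei(labels, labels.astype(float), pixel_size=1.0,
                             refine=False)
        assert obs[0].theta == pytest.approx(np.pi / 2, abs=1e-6)

    def test_uniform_disk_integrated_intensity(self):
        yy, xx = np.mgrid[0:50, 0:50]
        disk = (np.hypot(xx - 25, yy - 25) <= 10)
        labels = disk.astype(np.int32)
        img = np.where(disk, 7.0, 0.0)
        obs = measure_nuclei(labels, img, pixel_size=1.0, refine=False)
        assert obs[0].intensity == pytest.approx(7.0 * disk.sum())

    def test_rotation_equivariance(self, rendered_stack):
        cfg = SegmentationConfig()
        frame = rendered_stack.data[0]
        px = rendered_stack.pixel_size
        pre = preprocess(frame, cfg, px)
        obs = measure_nuclei(segment_nuclei(pre, cfg, px), frame, px,
                             refine_image=pre)
        rot_frame = np.rot90(frame)
        pre_r = preprocess(rot_frame, cfg, px)
        obs_r = measure_nuclei(segment_nuclei(pre_r, cfg, px), rot_frame, px,
                               refine_image=pre_r)
        areas = np.sort([o.area for o in obs])
        areas_r = np.sort([o.area for o in obs_r])
        n = min(len(areas), len(areas_r))
        assert len(areas) == pytest.approx(len(areas_r), abs=3)
        assert np.median(np.abs(areas[:n] - areas_r[:n]) / areas[:n]) < 0.01
        # thetas rotate by pi/2 (mod pi): compare sorted angle sets
        h, w = frame.shape
        mapped = sorted((o.theta + np.pi / 2) % np.pi for o in obs)
        measured = sorted(o.theta for o in obs_r)
        diffs = np.abs(np.array(mapped[:n]) - np.array(measured[:n]))
        assert np.median(np.minimum(diffs, np.pi - diffs)) < 0.1

    def test_empty_label_map(self):
        assert measure_nuclei(np.zeros((10, 10), np.int32),
                              np.zeros((10, 10)), 1.0) == []


def _obs(frame, label, x, y, area=50.0, j=100.0):
    return NucleusObservation(frame=frame, label=label, x=x, y=y, area=area,
                              theta=0.0, perimeter=25.0, intensity=j)


class TestLinking:
    def test_parallel_tracks_keep_identity(self):
        obs = []
        for t in range(10):
            obs.append([_obs(t, 1, 10 + 0.3 * t, 10.0),
                        _obs(t, 2, 10 + 0.3 * t, 20.0)])
        ts = link_tracks(obs, max_displacement=5.0)
        assert len(ts.track_ids) == 2
        for _, g in ts.df.groupby("track_id"):
            assert len(g) == 10
            assert g["y_um"].std() == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_brute_force_minimal_cost(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(3, 7)
        p0 = rng.uniform(0, 30, (n, 2))
        disp = rng.uniform(-2, 2, (n, 2))
        p1 = p0 + disp
        order = rng.permutation(n)
        obs = [[_obs(0, i + 1, *p0[i]) for i in range(n)],
               [_obs(1, i + 1, *p1[order[i]]) for i in range(n)]]
        ts = link_tracks(obs, max_displacement=10.0)
        # implementation cost
        cost = 0.0
        for _, g in ts.df.groupby("track_id"):
            if len(g) == 2:
                cost += ((g[["x_um", "y_um"]].diff().dropna() ** 2)
                         .sum().sum())
        # brute force
        a = np.array([[o.x, o.y] for o in obs[0]])
        b = np.array([[o.x, o.y] for o in obs[1]])
        best = min(sum(((a[i] - b[p[i]]) ** 2).sum() for i in range(n))
                   for p in itertools.permutations(range(n)))
        assert cost == pytest.approx(best, rel=1e-9)

    def test_jump_exceeding_max_displacement_starts_new_track(self):
        obs = [[_obs(0, 1, 0.0, 0.0)], [_obs(1, 1, 50.0, 0.0)]]
        ts = link_tracks(obs, max_displacement=5.0)
        assert len(ts.track_ids) == 2

    def test_order_permutation_invariance(self):
        rng = np.random.default_rng(5)
        frames = []
        for t in range(4):
            pts = [_obs(t, i + 1, 10.0 * i + 0.2 * t, 5.0 * i)
                   for i in range(5)]
            frames.append(pts)
        ref = link_tracks(frames, max_displacement=5.0)
        shuffled = [list(rng.permutation(f)) for f in frames]
        alt = link_tracks(shuffled, max_displacement=5.0)
        key = lambda ts: sorted(
            tuple(np.round(g[["x_um", "y_um"]].to_numpy().ravel(), 9))
            for _, g in ts.df.groupby("track_id"))
        assert key(ref) == key(alt)

    def test_nonpositive_displacement_rejected(self):
        with pytest.raises(ValueError):
            link_tracks([[], []], max_displacement=0.0)


class TestQualityFilter:
    def _track_with_intensity(self, j_values):
        obs = [[_obs(t, 1, 1.0 * t, 0.0, j=j)]
               for t, j in enumerate(j_values)]
        return link_tracks(obs, max_displacement=10.0)

    def test_fifteen_percent_deviation_flagged(self):
        j = [100.0] * 10 + [85.0]
        ts = apply_quality_filter(self._track_with_intensity(j))
        assert bool(ts.df["quality_flag"].iloc[10]) is True

    def test_five_percent_deviation_kept(self):
        j = [100.0] * 10 + [95.0]
        ts = apply_quality_filter(self._track_with_intensity(j))
        assert not ts.df["quality_flag"].any()

    def test_early_frames_never_flagged(self):
        j = [100.0, 300.0, 100.0, 50.0, 100.0]
        ts = apply_quality_filter(self._track_with_intensity(j))
        assert not ts.df["quality_flag"].any()

    def test_track_losing_over_20pct_excluded(self):
        # 100-frame track, 30 heavily deviating frames -> > 20 % flagged
        rng = np.random.default_rng(0)
        j = [100.0] * 100
        bad = rng.choice(np.arange(12, 100), size=40, replace=False)[:30]
        for b in bad:
            j[b] = 160.0
        ts = apply_quality_filter(self._track_with_intensity(j))
        flagged = ts.df["quality_flag"].sum()
        assert flagged / len(ts.df) > 0.2
        assert 0 in ts.excluded
        assert ts.usable().empty


class TestEndToEnd:
    def test_matched_track_accuracy(self):
        """Render → segment → track → filter recovers centroids to
        sub-half-pixel RMSE and areas to < 10 % median error."""
        cfg = nf.MonolayerConfig.flocking(n_cells=200, box_size=280,
                                          n_frames=12, seed=55)
        truth = nf.simulate_monolayer(cfg)
        stack = nf.render_frames(truth)
        obs = segtrack.segment_stack(stack)
        tracks = apply_quality_filter(link_tracks(
            obs, max_displacement=8.0, pixel_size=stack.pixel_size,
            dt=stack.dt))
        us = tracks.usable()
        px = stack.pixel_size
        r_nuc = np.sqrt(cfg.mean_nuclear_area / np.pi)
        errs, arel = [], []
        for t, grp in us.groupby("frame"):
            gt = truth.positions[t]
            cents = grp[["x_um", "y_um"]].to_numpy()
            areas = grp["area_um2"].to_numpy()
            dg, ig = cKDTree(cents).query(gt)
            ds, js = cKDTree(gt).query(cents)
            for g in range(len(gt)):
                if dg[g] < r_nuc and js[ig[g]] == g:
                    errs.append(dg[g] / px)
                    arel.append(abs(areas[ig[g]] - truth.areas[t, g])
                                / truth.areas[t, g])
        errs = np.asarray(errs)
        assert len(errs) > 1500
        assert np.sqrt((errs ** 2).mean()) < 0.5
        assert np.median(arel) < 0.10
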