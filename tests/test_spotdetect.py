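"""Detection engine: rectangle accounting, thresholding, colocalization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pimflux import (
    DetectParams,
    Particle,
    Rectangle,
    SimConfig,
    colocalize,
    detect_particles,
    detect_stack,
    measure_rectangle,
    quantify_particle,
    simulate_timelapse,
    z_average_project,
)
from pimflux.simkit import NoiseModel


def brute_force_rectangle(image, rect):
    """Independent pixel-loop oracle for the perimeter/interior accounting."""
    total, perim_sum, perim_n = 0.0, 0.0, 0
    for r in range(rect.row, rect.row + rect.height):
        for c in range(rect.col, rect.col + rect.width):
            total += float(image[r, c])
            on_perim = (r in (rect.row, rect.row + rect.height - 1)
                        or c in (rect.col, rect.col + rect.width - 1))
            if on_perim:
                perim_sum += float(image[r, c])
                perim_n += 1
    bg = perim_sum / perim_n
    return total - bg * rect.area, bg


class TestMeasureRectangle:
    def test_hand_computed_5x5_fixture(self):
        """Perimeter 2, interior 10: background 2, integrated 122 - 2*25 = 72."""
        img = np.full((5, 5), 2.0)
        img[1:4, 1:4] = 10.0
        integrated, background = measure_rectangle(img, Rectangle(0, 0, 5, 5))
        assert background == 2.0
        assert integrated == 72.0

    def test_constant_field_integrates_to_zero(self):
        for c in (0.0, 7.5, -3.0):
            integrated, background = measure_rectangle(
                np.full((9, 9), c), Rectangle(1, 2, 6, 5))
            assert integrated == pytest.approx(0.0, abs=1e-9)
            assert background == pytest.approx(c)

    def test_matches_brute_force_oracle_on_random_patches(self, rng):
        img = rng.integers(0, 1000, size=(40, 40)).astype(float)
        for _ in range(50):
            r = int(rng.integers(0, 33))
            c = int(rng.integers(0, 31))
            rect = Rectangle(r, c, 7, 9)
            got = measure_rectangle(img, rect)
            want = brute_force_rectangle(img, rect)
            assert got[0] == pytest.approx(want[0], abs=1e-9)
            assert got[1] == pytest.approx(want[1], abs=1e-9)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(a=st.floats(0.1, 50), b=st.floats(-100, 100), seed=st.integers(0, 10))
    def test_linearity(self, a, b, seed):
        """measure(a*img + b) = a*measure(img): the constant offset cancels."""
        img = np.random.default_rng(seed).uniform(0, 500, size=(12, 12))
        rect = Rectangle(2, 3, 6, 7)
        base, _ = measure_rectangle(img, rect)
        scaled, _ = measure_rectangle(a * img + b, rect)
        assert scaled == pytest.approx(a * base, rel=1e-9, abs=1e-6)

    def test_rectangle_outside_image_rejected(self):
        with pytest.raises(ValueError):
            measure_rectangle(np.zeros((10, 10)), Rectangle(5, 5, 6, 6))

    def test_degenerate_rectangle_rejected(self):
        with pytest.raises(ValueError):
            Rectangle(0, 0, 2, 5)


class TestDetectParticles:
    def test_noise_only_false_positive_rate(self, live_params, rng):
        """At SNR 20 a pure-noise field yields at most 1 hit per 10 frames."""
        mask = np.ones((256, 256), dtype=bool)
        hits = 0
        for _ in range(10):
            img = rng.normal(100.0, 10.0, size=(256, 256)).clip(0)
            hits += len(detect_particles(img, mask, live_params))
        assert hits <= 1

    def test_single_bright_spot_found_at_truth(self, live_params, rng):
        img = rng.normal(100.0, 2.0, size=(128, 128))
        yy, xx = np.mgrid[0:128, 0:128]
        img += 5000.0 / (2 * np.pi * 4) * np.exp(
            -((yy - 64.2) ** 2 + (xx - 40.7) ** 2) / (2 * 2.0 ** 2))
        found = detect_particles(img, np.ones_like(img, dtype=bool), live_params)
        assert len(found) == 1
        assert found[0].center[0] == pytest.approx(64.2, abs=1.0)
        assert found[0].center[1] == pytest.approx(40.7, abs=1.0)

    def test_area_boundary_four_pixels_rejected_five_kept(self):
        """'particles >4 pixels' is strict: area 4 out, area 5 in."""
        params = DetectParams(snr=5, min_area=4, smoothing_sigma=0.0,
                              merge_if_closer_than=0.0)
        base = np.zeros((32, 32))
        img4 = base.copy()
        img4[10:12, 10:12] = 1000.0           # 2x2 plateau, area 4
        assert detect_particles(img4, np.ones_like(base, bool), params) == []
        img5 = base.copy()
        img5[10:12, 10:12] = 1000.0
        img5[12, 10] = 1000.0                 # 5-pixel plateau
        assert len(detect_particles(img5, np.ones_like(base, bool), params)) == 1

    def test_empty_roi_and_constant_image(self, live_params):
        img = np.full((64, 64), 10.0)
        assert detect_particles(img, np.zeros((64, 64), bool), live_params) == []
        assert detect_particles(img, np.ones((64, 64), bool), live_params) == []

    def test_translation_equivariance(self, live_params, rng):
        img = rng.normal(100.0, 3.0, size=(128, 128))
        yy, xx = np.mgrid[0:128, 0:128]
        for r0, c0 in ((40.0, 50.0), (70.0, 30.0)):
            img += 6000.0 / (2 * np.pi * 4) * np.exp(
                -((yy - r0) ** 2 + (xx - c0) ** 2) / 8.0)
        shifted = np.roll(img, (7, -5), axis=(0, 1))
        mask = np.ones_like(img, dtype=bool)
        a = detect_particles(img, mask, live_params)
        b = detect_particles(shifted, mask, live_params)
        assert len(a) == len(b) == 2
        ca = sorted(p.center for p in a)
        cb = sorted(p.center for p in b)
        for (ra, caa), (rb, cbb) in zip(ca, cb):
            assert rb - ra == pytest.approx(7, abs=0.1)
            assert cbb - caa == pytest.approx(-5, abs=0.1)

    def test_smoothing_monotone_false_positives(self, rng):
        """Doubling the smoothing never raises the count on noise-only frames."""
        mask = np.ones((256, 256), dtype=bool)
        imgs = [rng.normal(100.0, 10.0, size=(256, 256)) for _ in range(5)]
        for snr in (5.0, 20.0):
            n1 = sum(len(detect_particles(im, mask, DetectParams(snr=snr, smoothing_sigma=1.0)))
                     for im in imgs)
            n2 = sum(len(detect_particles(im, mask, DetectParams(snr=snr, smoothing_sigma=2.0)))
                     for im in imgs)
            assert n2 <= n1

    def test_recall_precision_on_simulated_isolated_spots(self):
        """>= 95% recall and precision against simulator ground truth."""
        from scipy.spatial import cKDTree

        recalls, precisions = [], []
        for seed in (0, 1, 2):
            cfg = SimConfig(
                image_shape=(256, 256), n_frames=4, frame_interval=10.0,
                clusters_per_cell_mean=55, min_separation=10,
                clearance_rate=0.0, drift_speed=0.0, drift_jitter=0.0, seed=seed)
            stack, log = simulate_timelapse(cfg)
            parts = detect_stack(stack, DetectParams(snr=20), quantify=False)
            for f in range(cfg.n_frames):
                truth = log.records[(log.records["frame"] == f) & log.records["active"]]
                det = [p for p in parts if p.frame == f]
                tree = cKDTree(truth[["row", "col"]].to_numpy())
                matched_truth = set()
                tp = 0
                for p in det:
                    d, i = tree.query(p.center)
                    if d <= 3.0 and i not in matched_truth:
                        matched_truth.add(i)
                        tp += 1
                recalls.append(tp / len(truth))
                precisions.append(tp / max(len(det), 1))
        assert min(recalls) >= 0.95
        assert min(precisions) >= 0.95


class TestQuantifyParticle:
    def _particle(self, rect):
        return Particle(id=0, cell_id=1, frame=0, rectangle=rect,
                        center=rect.center, area=9)

    def test_zero_egfp_channel(self, small_wt_run):
        _, stack, _ = small_wt_run
        import copy

        st2 = copy.copy(stack)
        st2.pixels = stack.pixels.copy()
        st2.pixels[:, 1] = 0
        p = quantify_particle(st2, self._particle(Rectangle(20, 20, 9, 9)))
        assert p.I_egfp == 0.0

    def test_identical_channels_give_identical_integrals(self, small_wt_run):
        import copy

        _, stack, _ = small_wt_run
        st2 = copy.copy(stack)
        st2.pixels = stack.pixels.copy()
        st2.pixels[:, 1] = st2.pixels[:, 0]
        p = quantify_particle(st2, self._particle(Rectangle(100, 100, 11, 11)))
        assert p.I_egfp == p.I_mcherry

    def test_ratio_matches_simulated_amplitude_ratio(self):
        """Noise off: measured I_egfp/I_mcherry equals the true amplitude ratio within 2%."""
        cfg = SimConfig(image_shape=(96, 96), n_frames=1, clusters_per_cell_mean=1,
                        initial_ratio_mean=0.7, initial_ratio_sd=0.0,
                        drift_speed=0.0, drift_jitter=0.0,
                        noise=NoiseModel(background=100.0, read_sd=0.0, poisson=False),
                        seed=5)
        stack, log = simulate_timelapse(cfg, noise=False)
        cl = log.records.iloc[0]
        r, c = int(round(cl["row"])), int(round(cl["col"]))
        p = self._particle(Rectangle(r - 8, c - 8, 17, 17))
        quantify_particle(stack, p)
        assert p.I_egfp / p.I_mcherry == pytest.approx(0.7, rel=0.02)

    def test_missing_channel_is_hard_error(self, small_wt_run):
        import copy

        _, stack, _ = small_wt_run
        st2 = copy.copy(stack)
        st2.channels = ("mCherry",)
        st2.pixels = stack.pixels[:, :1]
        with pytest.raises(KeyError):
            quantify_particle(st2, self._particle(Rectangle(10, 10, 9, 9)))


class TestColocalize:
    def _make(self, centers):
        return [Particle(id=i, cell_id=1, frame=0,
                         rectangle=Rectangle(0, 0, 5, 5), center=c, area=9)
                for i, c in enumerate(centers)]

    def test_identical_lists_all_colocalized(self):
        prim = self._make([(10.0, 10.0), (40.0, 12.0), (70.0, 33.0)])
        flags, fractions = colocalize(
            prim, self._make([p.center for p in prim]), max_dist=2.0,
            colors={0: "yellow", 1: "yellow", 2: "red"})
        assert flags == [True, True, True]
        assert fractions == {"yellow": 1.0, "red": 1.0}

    def test_all_far_apart_gives_zero_fractions(self):
        prim = self._make([(10.0, 10.0), (40.0, 12.0)])
        marker = self._make([(100.0, 100.0)])
        flags, fractions = colocalize(prim, marker, max_dist=5.0,
                                      colors={0: "yellow", 1: "yellow"})
        assert flags == [False, False]
        assert fractions["yellow"] == 0.0
        assert fractions["red"] is None     # empty class is missing, not 0

    def test_empty_marker_list(self):
        prim = self._make([(10.0, 10.0)])
        flags, _ = colocalize(prim, [], max_dist=5.0)
        assert flags == [False]

    def test_matches_brute_force_oracle(self, rng):
        """Greedy nearest-first one-to-one matching against an exhaustive oracle."""
        for _ in range(5):
            prim = self._make([tuple(x) for x in rng.uniform(0, 100, size=(30, 2))])
            marker = self._make([tuple(x) for x in rng.uniform(0, 100, size=(25, 2))])
            max_dist = 8.0
            flags, _ = colocalize(prim, marker, max_dist)
            # oracle: same greedy nearest-first policy, explicit all-pairs loop
            pairs = []
            for i, p in enumerate(prim):
                for j, m in enumerate(marker):
                    d = np.hypot(p.center[0] - m.center[0], p.center[1] - m.center[1])
                    if d <= max_dist:
                        pairs.append((d, i, j))
            expect = [False] * len(prim)
            used_p, used_m = set(), set()
            for d, i, j in sorted(pairs):
                if i not in used_p and j not in used_m:
                    expect[i] = True
                    used_p.add(i)
                    used_m.add(j)
            assert flags == expect


class TestZProjection:
    def test_constant_planes_average(self):
        stack = np.stack([np.full((8, 8), v, dtype=float) for v in range(1, 8)])
        np.testing.assert_allclose(z_average_project(stack), 4.0)

    def test_single_plane_identity(self, rng):
        plane = rng.uniform(size=(16, 16))
        np.testing.assert_array_equal(z_average_project(plane[None]), plane)

    def test_matches_pixel_loop_oracle(self, rng):
        stack = rng.uniform(0, 100, size=(7, 6, 5))
        got = z_average_project(stack)
        for r in range(6):
            for c in range(5):
                assert got[r, c] == pytest.approx(
                    sum(stack[z, r, c] for z in range(7)) / 7.0, abs=1e-12)

    def test_bad_input_rejected(self):
        with pytest.raises(ValueError):
            z_average_project(np.zeros((4, 4)))
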