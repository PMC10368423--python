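"""Tests for the MS2 movie processing stages."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wavegrn import ms2_imaging as ms2


def blob2d(shape, cy, cx, sigma=5.0, peak=100.0):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    return peak * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2))


def blob3d(shape, cz, cy, cx, sigma=1.2, peak=50.0):
    zz, yy, xx = np.mgrid[: shape[0], : shape[1], : shape[2]]
    return peak * np.exp(
        -((zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2)
    )


class TestMaxProject:
    def test_single_plane_identity(self, rng):
        data = rng.uniform(0, 1, (3, 1, 8, 8))
        np.testing.assert_array_equal(
            ms2.max_project(ms2.MovieStack(data=data)), data[:, 0]
        )

    def test_equals_bruteforce_per_pixel_max(self, rng):
        data = rng.uniform(0, 10, (2, 5, 6, 7))
        proj = ms2.max_project(ms2.MovieStack(data=data))
        for t in range(2):
            for y in range(6):
                for x in range(7):
                    assert proj[t, y, x] == max(data[t, z, y, x] for z in range(5))


class TestEnhanceContrast:
    def test_constant_image_unchanged(self):
        out = ms2.enhance_contrast(np.full((64, 64), 7.0))
        assert np.unique(out).size == 1

    def test_output_range(self, rng):
        out = ms2.enhance_contrast(rng.uniform(0, 255, (100, 150)))
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_monotone_ordering_preserved_on_gradient(self):
        img = np.tile(np.linspace(0, 100, 64), (64, 1))
        out = ms2.enhance_contrast(img, block_size=64)
        row = out[32]
        assert np.all(np.diff(row) >= -1e-9)

    def test_oversized_block_warns(self):
        with pytest.warns(UserWarning, match="block_size"):
            ms2.enhance_contrast(np.eye(32), block_size=128)


class TestSegmentNuclei:
    def test_half_max_rule_excludes_dim_blob(self):
        img = blob2d((80, 80), 25, 25, peak=100) + blob2d((80, 80), 55, 55, peak=40)
        lm = ms2.segment_nuclei(img)
        assert lm.n_nuclei == 1

    def test_equal_blobs_centroids(self):
        img = blob2d((80, 120), 40, 30) + blob2d((80, 120), 40, 90)
        lm = ms2.segment_nuclei(img)
        assert lm.n_nuclei == 2
        found = np.array(sorted(lm.centroids.values(), key=lambda c: c[1]))
        np.testing.assert_allclose(found, [[40, 30], [40, 90]], atol=2.0)

    def test_labels_partition_claimed_pixels(self):
        img = blob2d((60, 60), 20, 20) + blob2d((60, 60), 40, 45)
        lm = ms2.segment_nuclei(img)
        labels = lm.labels
        assert labels.min() >= 0
        assert set(np.unique(labels)) - {0} == set(lm.centroids)
        for lab, (cy, cx) in lm.centroids.items():
            assert 0 <= cy < 60 and 0 <= cx < 60

    def test_zero_image_empty_map(self):
        lm = ms2.segment_nuclei(np.zeros((32, 32)))
        assert lm.n_nuclei == 0
        assert not lm.labels.any()


class TestDetectSpots:
    def test_zero_volume_no_spots(self):
        assert ms2.detect_spots(np.zeros((10, 20, 20)), threshold=0.1) == []

    def test_single_punctum_located(self):
        vol = blob3d((16, 40, 40), 8, 21.0, 17.0)
        spots = ms2.detect_spots(vol, threshold=1.0)
        assert len(spots) == 1
        s = spots[0]
        assert abs(s.z - 8) <= 1 and abs(s.y - 21) <= 1 and abs(s.x - 17) <= 1
        assert s.intensity > 0

    def test_tolerance_merges_adjacent_pair(self):
        # a dimmer punctum adjacent to a brighter one merges into it when it
        # stands above the connecting saddle by less than the tolerance
        from scipy.ndimage import gaussian_filter

        vol = blob3d((12, 30, 30), 6, 15, 12, peak=50) + blob3d(
            (12, 30, 30), 6, 15, 18, peak=35
        )
        dog = gaussian_filter(vol, 1.2) - gaussian_filter(vol, 2.4)
        saddle = dog[6, 15, 14:17].min()
        prominence = dog[6, 15, 18] - saddle  # dim peak over the saddle
        merged = ms2.detect_spots(vol, tolerance=1.2 * prominence, threshold=0.5)
        split = ms2.detect_spots(vol, tolerance=0.5 * prominence, threshold=0.5)
        assert len(merged) == 1
        assert merged[0].x == 12  # the bright punctum survives
        assert len(split) == 2

    def test_matches_bruteforce_maxima_scan(self, rng):
        # with no tolerance pruning, spots are exactly the strict local
        # maxima of the DoG above threshold (away from the border)
        from scipy.ndimage import gaussian_filter, maximum_filter

        vol = rng.uniform(0, 1, (10, 24, 24))
        vol += blob3d((10, 24, 24), 5, 10, 12, peak=30)
        thr = 1.0
        spots = ms2.detect_spots(vol, tolerance=0.0, threshold=thr)
        dog = gaussian_filter(vol, 1.2) - gaussian_filter(vol, 2.4)
        mx = (dog == maximum_filter(dog, size=3)) & (dog >= thr)
        mx[0] = mx[-1] = False
        mx[:, 0] = mx[:, -1] = False
        mx[:, :, 0] = mx[:, :, -1] = False
        expected = set(map(tuple, np.argwhere(mx)))
        got = {(int(s.z), int(s.y), int(s.x)) for s in spots}
        assert got == expected

    def test_invalid_sigmas(self):
        with pytest.raises(ValueError):
            ms2.detect_spots(np.zeros((4, 4, 4)), sigma_small=2.0, sigma_large=1.0)


class TestAssignSpots:
    def make_labels(self):
        labels = np.zeros((40, 40), dtype=int)
        labels[5:15, 5:15] = 1
        labels[25:35, 25:35] = 2
        return ms2.NucleusLabelMap(
            labels=labels, centroids={1: (10.0, 10.0), 2: (30.0, 30.0)}
        )

    def spot(self, y, x, intensity=5.0):
        return ms2.SpotRecord(t=0, z=0, y=y, x=x, intensity=intensity, dog_value=1.0)

    def test_inside_region(self):
        s = self.spot(8, 9)
        ms2.assign_spots([s], self.make_labels())
        assert s.nucleus_id == 1

    def test_background_beyond_radius_unassigned(self):
        s = self.spot(0, 39)
        ms2.assign_spots([s], self.make_labels(), max_radius=5.0)
        assert s.nucleus_id is None

    def test_background_near_centroid_assigned(self):
        s = self.spot(17, 10)  # just outside region 1
        ms2.assign_spots([s], self.make_labels(), max_radius=10.0)
        assert s.nucleus_id == 1

    def test_brightest_wins_per_nucleus(self):
        a, b = self.spot(8, 9, intensity=5.0), self.spot(10, 11, intensity=9.0)
        ms2.assign_spots([a, b], self.make_labels())
        assert a.nucleus_id == b.nucleus_id == 1
        assert a.flagged and not b.flagged


class TestTrackNuclei:
    def lmap(self, centroids):
        labels = np.zeros((64, 64), dtype=int)
        cents = {}
        for i, (y, x) in enumerate(centroids, start=1):
            labels[int(y), int(x)] = i
            cents[i] = (float(y), float(x))
        return ms2.NucleusLabelMap(labels=labels, centroids=cents)

    def test_stationary_nuclei(self):
        maps = [self.lmap([(10, 10), (40, 40)]) for _ in range(3)]
        tracks = ms2.track_nuclei(maps)
        assert len(tracks) == 2
        assert all(len(t) == 3 for t in tracks)

    def test_slow_motion_single_track(self):
        maps = [self.lmap([(10 + f, 10 + 2 * f)]) for f in range(6)]
        tracks = ms2.track_nuclei(maps, max_displacement=5.0)
        assert len(tracks) == 1 and len(tracks[0]) == 6

    def test_jump_terminates_track(self):
        maps = [self.lmap([(10, 10)])] * 3 + [self.lmap([(50, 50)])] * 3
        tracks = ms2.track_nuclei(maps, max_displacement=8.0)
        assert len(tracks) == 2
        assert sorted(len(t) for t in tracks) == [3, 3]

    def test_greedy_equals_optimal_when_separated(self, rng):
        for _ in range(10):
            pos = rng.uniform(10, 54, (4, 2))
            maps = []
            for f in range(5):
                maps.append(self.lmap(pos + rng.uniform(-1.5, 1.5, (4, 2)) * f * 0.2))
            greedy = ms2.track_nuclei(maps, max_displacement=6.0)
            optimal = ms2.track_nuclei(maps, max_displacement=6.0, optimal=True)
            key = lambda ts: sorted(tuple(t.centroids[0]) for t in ts)
            assert key(greedy) == key(optimal)
            assert sorted(len(t) for t in greedy) == sorted(len(t) for t in optimal)

    def test_needs_two_frames(self):
        with pytest.raises(ValueError):
            ms2.track_nuclei([self.lmap([(5, 5)])])


class TestEstimateMrna:
    def track(self, intensities):
        n = len(intensities)
        return ms2.NucleusTrack(
            track_id=0,
            frames=list(range(n)),
            centroids=[(0.0, 0.0)] * n,
            intensities=list(intensities),
        )

    def test_constant_series(self):
        est = ms2.estimate_mrna(self.track([3.0] * 25), window=10)
        np.testing.assert_allclose(est.values, 3.0)

    def test_unit_impulse_interior(self):
        x = [0.0] * 30
        x[15] = 1.0
        est = ms2.estimate_mrna(self.track(x), window=10)
        covered = est.values > 0
        assert covered.sum() == 10
        np.testing.assert_allclose(est.values[covered], 0.1)

    @given(
        st.lists(st.floats(0, 10), min_size=1, max_size=40),
        st.integers(1, 12),
    )
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_matches_bruteforce_windowed_mean(self, series, window):
        est = ms2.estimate_mrna(self.track(series), window=window)
        before, after = (window - 1) // 2, window // 2
        for i in range(len(series)):
            lo, hi = max(0, i - before), min(len(series), i + after + 1)
            assert est.values[i] == pytest.approx(np.mean(series[lo:hi]))

    def test_empty_track_rejected(self):
        with pytest.raises(ValueError):
            ms2.estimate_mrna(self.track([]), window=10)


class TestEndToEnd:
    def test_noiseless_single_nucleus_movie(self):
        from wavegrn import synthetic as syn

        movie, truth = syn.gen_embryo_movie(
            lambda x, t: np.ones_like(x),
            n_nuclei=1,
            frames=5,
            shape=(12, 48, 48),
            drift=(0.0, 0.0),
            walk_sigma=0.0,
            poisson_noise=False,
            snr=8.0,
            seed=3,
        )
        for f in range(5):
            spots = ms2.detect_spots(movie.data[f], tolerance=0.2, threshold=0.5)
            assert len(spots) == 1
            true = truth.spots_at(f)[0]
            assert np.hypot(spots[0].y - true[1], spots[0].x - true[2]) <= 1.5

    def test_pipeline_scores_on_benchmark_movies(self, imaging_benchmark_results):
        for wave, res in imaging_benchmark_results.items():
            assert res["recall"] >= 0.9, wave
            assert res["precision"] >= 0.9, wave
            assert res["track_identity_preservation"] >= 0.95, wave
            assert res["mean_pearson_r"] >= 0.8, wave
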