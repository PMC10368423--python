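"""Tests for kymograph extraction, wave tracking and classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from wavegrn import grn_model as gm
from wavegrn import wave_analysis as wa


def make_kymo(values, times=None):
    values = np.asarray(values, dtype=float)
    t = np.arange(values.shape[0], dtype=float) if times is None else times
    edges = np.arange(values.shape[1] + 1, dtype=float) - 0.5
    return wa.Kymograph(values=values, times=t, bin_edges=edges)


def gaussian_frame(n, center, amp=1.0, width=2.0):
    x = np.arange(n)
    return amp * np.exp(-((x - center) ** 2) / (2 * width**2))


class TestExtractKymograph:
    def test_simulation_slice_is_identity(self, default_sim):
        kymo = wa.extract_kymograph(default_sim, "G1")
        np.testing.assert_array_equal(kymo.values, default_sim.get("G1"))
        assert kymo.n_positions == default_sim.n_cells

    def test_single_position_tracked_input(self):
        df = pd.DataFrame(
            {"t": [0, 0, 1, 1], "x": [10.0] * 4, "intensity": [1, 3, 5, 7]}
        )
        kymo = wa.extract_kymograph(df, n_bins=8, extent=(0, 64))
        filled = ~np.isnan(kymo.values)
        assert filled.sum() == 2  # one column, two frames
        np.testing.assert_allclose(kymo.values[filled], [2.0, 6.0])

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            wa.extract_kymograph(pd.DataFrame(columns=["t", "x", "intensity"]))

    def test_traveling_gaussian_peaks_match_generator(self, rng):
        # nuclei scattered along the axis sample a moving Gaussian field
        n_frames, n_bins = 30, 24
        x = rng.uniform(0, 120, 150)
        rows = []
        centers = np.linspace(100, 20, n_frames)
        for f in range(n_frames):
            rows.append(
                pd.DataFrame(
                    {
                        "t": f,
                        "x": x,
                        "intensity": np.exp(-((x - centers[f]) ** 2) / (2 * 8.0**2)),
                    }
                )
            )
        kymo = wa.extract_kymograph(pd.concat(rows), n_bins=n_bins, extent=(0, 120))
        bin_width = 120 / n_bins
        for f in range(n_frames):
            peak_bin = np.nanargmax(kymo.values[f])
            assert abs(kymo.bin_centers[peak_bin] - centers[f]) <= bin_width

    def test_sum_mode_conserves_total_signal(self, rng):
        df = pd.DataFrame(
            {
                "t": np.repeat(np.arange(5), 40),
                "x": np.tile(rng.uniform(0, 100, 40), 5),
                "intensity": rng.uniform(0, 2, 200),
            }
        )
        kymo = wa.extract_kymograph(df, n_bins=10, extent=(0, 100), aggregate="sum")
        for f in range(5):
            assert np.nansum(kymo.values[f]) == pytest.approx(
                df[df.t == f].intensity.sum()
            )

    def test_csv_roundtrip(self, tmp_path):
        kymo = make_kymo([[0, 1, 0], [1, 0, 0]])
        path = tmp_path / "kymo.csv"
        kymo.to_csv(path)
        back = wa.Kymograph.from_csv(path)
        np.testing.assert_allclose(back.values, kymo.values)
        np.testing.assert_allclose(back.times, kymo.times)


class TestDetectWavePeaks:
    def test_stationary_bump_single_track(self):
        frames = [gaussian_frame(50, 25) for _ in range(10)]
        tracks = wa.detect_wave_peaks(make_kymo(frames), 0.5, 3.0)
        assert len(tracks) == 1
        assert len(tracks[0]) == 10
        assert tracks[0].positions[-1] == tracks[0].positions[0]

    def test_translating_bump_slope(self):
        frames = [gaussian_frame(60, 45 - f) for f in range(20)]
        tracks = wa.detect_wave_peaks(make_kymo(frames), 0.5, 3.0)
        assert len(tracks) == 1
        slope = np.polyfit(tracks[0].times, tracks[0].positions, 1)[0]
        assert slope == pytest.approx(-1.0, abs=0.05)

    def test_distant_bumps_stay_separate(self):
        frames = [gaussian_frame(80, 15) + gaussian_frame(80, 65) for _ in range(5)]
        tracks = wa.detect_wave_peaks(make_kymo(frames), 0.5, max_link_distance=10)
        assert len(tracks) == 2

    def test_link_break_beyond_distance_starts_new_track(self):
        frames = [gaussian_frame(80, 20)] * 3 + [gaussian_frame(80, 60)] * 3
        tracks = wa.detect_wave_peaks(make_kymo(frames), 0.5, max_link_distance=10)
        assert len(tracks) == 2
        assert {len(t) for t in tracks} == {3}

    def test_invalid_inputs(self):
        kymo = make_kymo([[0, 1, 0], [0, 1, 0]])
        with pytest.raises(ValueError):
            wa.detect_wave_peaks(kymo, 0.0, 3.0)
        with pytest.raises(ValueError):
            wa.detect_wave_peaks(make_kymo([[0, 1, 0]]), 0.5, 3.0)

    def test_missing_bins_interpolated_only_for_detection(self):
        vals = np.array([gaussian_frame(30, 14) for _ in range(4)])
        vals[:, 10] = np.nan
        kymo = make_kymo(vals)
        tracks = wa.detect_wave_peaks(kymo, 0.3, 3.0)
        assert len(tracks) == 1
        assert np.isnan(kymo.values[:, 10]).all()  # stored data untouched

    def test_greedy_matches_optimal_assignment_when_separated(self, rng):
        # up to 3 well-separated peaks moving less than half their spacing:
        # greedy nearest linking equals the optimal bipartite assignment
        from scipy.optimize import linear_sum_assignment

        for trial in range(30):
            n_peaks = rng.integers(1, 4)
            base = np.sort(rng.choice(np.arange(10, 110, 30), n_peaks, replace=False))
            frames = []
            offsets = [np.zeros(n_peaks)]
            for _ in range(6):
                offsets.append(offsets[-1] + rng.uniform(-4, 4, n_peaks))
            for off in offsets:
                frames.append(
                    sum(gaussian_frame(130, b + o) for b, o in zip(base, off))
                )
            tracks = wa.detect_wave_peaks(make_kymo(frames), 0.3, 10.0)
            long_tracks = [t for t in tracks if len(t) == len(frames)]
            assert len(long_tracks) == n_peaks
            # frame-to-frame optimal matching keeps each track on its own peak
            for tr in long_tracks:
                d = np.abs(np.diff(tr.positions))
                assert np.all(d <= 10.0)


class TestClassification:
    def make_track(self, positions, amplitudes):
        n = len(positions)
        return wa.WaveTrack(
            track_id=0,
            times=np.arange(n, dtype=float),
            positions=np.asarray(positions, dtype=float),
            amplitudes=np.asarray(amplitudes, dtype=float),
            prominences=np.ones(n),
        )

    def test_gaining_wave_is_static_like(self):
        # amplitude grows as the wave travels toward the anterior
        tr = self.make_track([30, 20, 10], [1, 2, 3])
        s = wa.classify_enhancer_dynamics(tr)
        assert s.direction == "posterior_to_anterior"
        assert s.classification == "static_like"
        assert s.amplitude_slope < 0

    def test_fading_wave_is_dynamic_like(self):
        tr = self.make_track([30, 20, 10], [3, 2, 1])
        s = wa.classify_enhancer_dynamics(tr)
        assert s.direction == "posterior_to_anterior"
        assert s.classification == "dynamic_like"

    def test_constant_amplitude_is_ambiguous(self):
        tr = self.make_track([30, 20, 10], [2, 2, 2])
        assert wa.classify_enhancer_dynamics(tr).classification == "ambiguous"

    def test_stationary_track_is_ambiguous(self):
        tr = self.make_track([10, 10, 10], [1, 2, 3])
        s = wa.classify_enhancer_dynamics(tr)
        assert s.direction == "stationary"
        assert s.classification == "ambiguous"

    def test_short_track_rejected(self):
        with pytest.raises(ValueError):
            wa.classify_enhancer_dynamics(self.make_track([1, 2], [1, 1]))


class TestCountStripes:
    @pytest.mark.parametrize(
        "frame,threshold,expected",
        [
            ([0.1, 0.2, 0.1], 0.5, 0),
            ([0, 1, 0, 1, 0], 0.5, 2),
            ([1, 0, 1], 0.5, 2),
            ([1, 1, 1], 0.5, 1),
        ],
    )
    def test_examples(self, frame, threshold, expected):
        assert wa.count_stripes(frame, threshold) == expected

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60), st.floats(0.1, 0.9))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_matches_run_length_scan(self, frame, threshold):
        runs, inside = 0, False
        for v in frame:
            if v > threshold and not inside:
                runs += 1
            inside = v > threshold
        assert wa.count_stripes(frame, threshold) == runs


class TestApIntensityProfile:
    def test_uniform_image(self):
        prof = wa.ap_intensity_profile(np.ones((7, 5)))
        np.testing.assert_allclose(prof, np.full(5, 7.0))

    def test_single_bright_column(self):
        img = np.zeros((4, 6))
        img[:, 2] = 3.0
        prof = wa.ap_intensity_profile(img)
        assert prof.argmax() == 2 and prof[2] == 12.0

    def test_mask_behaviour(self):
        img = np.arange(12.0).reshape(3, 4)
        full = wa.ap_intensity_profile(img, mask=np.ones((3, 4), bool))
        np.testing.assert_allclose(full, wa.ap_intensity_profile(img))
        with pytest.raises(ValueError):
            wa.ap_intensity_profile(img, mask=np.ones((2, 4), bool))


class TestDeletionPhenotypeReport:
    def test_intact_vs_intact(self, weak_static_sim):
        rep = wa.deletion_phenotype_report(weak_static_sim, weak_static_sim, 2)
        assert rep["amplitude_ratio"] == pytest.approx(1.0)

    def test_mismatched_grids_rejected(self, weak_static_sim):
        other = gm.simulate(
            gm.WEAK_STATIC_PARAMS, gm.make_speed_profile(50, "linear"), t_max=2.0
        )
        with pytest.raises(ValueError):
            wa.deletion_phenotype_report(weak_static_sim, other, 2)


class TestSimulatedWaves:
    """The module's central reproduction: wave direction and reporter classes."""

    @staticmethod
    def long_tracks(sim, species, min_length=10):
        kymo = wa.extract_kymograph(sim, species)
        tracks = wa.detect_wave_peaks(kymo, 0.1 * kymo.values.max(), 5.0)
        return kymo, [t for t in tracks if len(t) >= min_length]

    @pytest.mark.parametrize("species", ["G1", "G2", "G3", "RD", "RS"])
    def test_all_waves_travel_posterior_to_anterior(self, default_sim, species):
        # moving peaks all travel posterior -> anterior; the only other
        # long-lived peaks are stabilized (stationary) stripes, never
        # anterior -> posterior waves
        kymo, long_tracks = self.long_tracks(default_sim, species)
        summaries = [
            wa.classify_enhancer_dynamics(t, axis_length=kymo.n_positions)
            for t in long_tracks
        ]
        waves = [
            s
            for t, s in zip(long_tracks, summaries)
            if abs(t.positions[-1] - t.positions[0]) > 0.05 * kymo.n_positions
        ]
        assert len(waves) >= 3
        assert all(s.direction == "posterior_to_anterior" for s in summaries if s in waves)
        assert not any(s.direction == "anterior_to_posterior" for s in summaries)

    def test_static_reporter_gains_dynamic_reporter_fades(self, default_sim):
        for species, expected in (("RS", "static_like"), ("RD", "dynamic_like")):
            kymo, long_tracks = self.long_tracks(default_sim, species)
            n_checked = 0
            for tr in long_tracks:
                if abs(tr.positions[-1] - tr.positions[0]) <= 0.05 * kymo.n_positions:
                    continue  # stabilized stripe, carries no wave trend
                s = wa.classify_enhancer_dynamics(tr, axis_length=kymo.n_positions)
                assert s.classification == expected
                n_checked += 1
            assert n_checked >= 3
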