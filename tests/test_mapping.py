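"""RMS maps, equalization, watershed segmentation, barycenters."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import emgrid as eg
from conftest import single_source_recording
from emgrid.errors import (
    EmptySelectionError,
    InsufficientDataError,
    InvalidMetadataError,
)
from emgrid.mapping import AmplitudeMap
from emgrid.preprocess import EpochWindow


def gaussian_map(layout, center, spread=10.0, amp=1.0):
    d2 = np.sum((layout.positions - np.asarray(center, float)) ** 2, axis=1)
    return amp * np.exp(-d2 / (2 * spread**2))


class TestComputeRmsMap:
    def test_constant_signal_rms_is_magnitude(self, small_layout):
        data = np.full((200, small_layout.n_channels), -3.0)
        rec = eg.Recording(data=data, fs=100.0)
        amap = eg.compute_rms_map(rec, EpochWindow(0, 200), small_layout)
        assert np.allclose(amap.values, 3.0)

    def test_unit_sine_rms_is_inverse_sqrt2(self, small_layout):
        fs = 256.0
        t = np.arange(int(fs)) / fs  # exactly 8 periods of 8 Hz
        s = np.sin(2 * np.pi * 8 * t)
        data = np.tile(s[:, None], (1, small_layout.n_channels))
        rec = eg.Recording(data=data, fs=fs)
        amap = eg.compute_rms_map(rec, EpochWindow(0, len(t)), small_layout)
        assert np.allclose(amap.values, 1 / np.sqrt(2), rtol=1e-3)

    def test_zero_recording_gives_zero_map(self, small_layout):
        rec = eg.Recording(data=np.zeros((64, small_layout.n_channels)), fs=64.0)
        amap = eg.compute_rms_map(rec, EpochWindow(0, 64), small_layout)
        assert np.all(amap.values == 0.0)

    def test_empty_or_out_of_bounds_window_errors(self, small_layout):
        rec = eg.Recording(data=np.zeros((64, small_layout.n_channels)), fs=64.0)
        with pytest.raises(InsufficientDataError):
            eg.compute_rms_map(rec, EpochWindow(10, 10), small_layout)
        with pytest.raises(InsufficientDataError):
            eg.compute_rms_map(rec, EpochWindow(0, 100), small_layout)


class TestEqualizeMap:
    def test_range_is_zero_to_one(self, standard):
        amap = AmplitudeMap(gaussian_map(standard, (30, 50)), standard)
        eq = eg.equalize_map(amap)
        assert eq.values.min() == 0.0
        assert eq.values.max() == 1.0

    def test_distinct_values_get_uniform_ranks(self, standard):
        rng = np.random.default_rng(0)
        v = rng.permutation(128).astype(float)  # 128 distinct values
        eq = eg.equalize_map(AmplitudeMap(v, standard))
        # explicit sort oracle: value of rank r -> (r-1)/127
        order = np.argsort(v)
        expect = np.empty(128)
        expect[order] = np.arange(128) / 127.0
        assert np.allclose(eq.values, expect)

    @given(st.lists(st.floats(0, 1e6, allow_nan=False), min_size=2, max_size=36))
    def test_monotone_in_input(self, vals):
        lay = eg.build_grid(eg.GridSpec(n_rows=6, n_cols=6, pitch_mm=10.0))
        v = np.resize(np.asarray(vals), lay.n_channels)
        eq = eg.equalize_map(AmplitudeMap(v, lay)).values
        for i in range(len(v)):
            for j in range(len(v)):
                if v[i] < v[j]:
                    assert eq[i] < eq[j]
                elif v[i] == v[j]:
                    assert eq[i] == eq[j]

    def test_constant_map_degenerates_to_single_cluster(self, standard):
        amap = AmplitudeMap(np.full(128, 2.5), standard)
        eq = eg.equalize_map(amap)
        assert np.all(eq.values == eq.values[0])
        labels = eg.segment_map(amap)
        assert set(labels[labels > 0]) == {1}
        assert np.all(labels > 0)


class TestSegmentMap:
    def test_single_noiseless_blob_is_one_cluster(self, standard):
        amap = AmplitudeMap(gaussian_map(standard, (30.0, 50.0)), standard)
        labels = eg.segment_map(amap)
        assert len(np.unique(labels[labels > 0])) == 1

    def test_cluster_count_equals_regional_maxima_count(self, standard):
        """The number of watershed clusters equals the number of
        regional maxima of the equalized map (the flooding seeds)."""
        from skimage.measure import label as sk_label
        from skimage.morphology import local_maxima

        rng = np.random.default_rng(3)
        v = gaussian_map(standard, (30.0, 50.0)) + np.abs(rng.normal(0, 0.05, 128))
        amap = AmplitudeMap(v, standard)
        labels = eg.segment_map(amap)
        g = eg.equalize_map(amap).to_grid(fill=-1.0)
        seeds = sk_label(
            local_maxima(g, connectivity=2) & standard.valid_mask, connectivity=2
        )
        assert len(np.unique(labels[labels > 0])) == seeds.max()

    def test_two_distant_blobs_give_two_clusters(self, standard):
        v = gaussian_map(standard, (0.0, 30.0)) + gaussian_map(standard, (60.0, 90.0))
        amap = AmplitudeMap(v, standard)
        labels = eg.segment_map(amap)
        ids = np.unique(labels[labels > 0])
        assert len(ids) == 2
        # each cluster contains its blob's peak electrode
        for center in [(0.0, 30.0), (60.0, 90.0)]:
            i = int(np.argmin(np.linalg.norm(standard.positions - center, axis=1)))
            peak_label = labels[i]
            assert peak_label in ids
        i1 = int(np.argmin(np.linalg.norm(standard.positions - (0.0, 30.0), axis=1)))
        i2 = int(np.argmin(np.linalg.norm(standard.positions - (60.0, 90.0), axis=1)))
        assert labels[i1] != labels[i2]

    def test_labels_partition_valid_cells(self, standard):
        rng = np.random.default_rng(9)
        amap = AmplitudeMap(rng.random(128), standard)
        labels = eg.segment_map(amap)
        assert labels.shape == (128,)
        assert np.all(labels >= 1)  # every valid cell labeled exactly once


class TestPrimaryClusterAndThreshold:
    def test_highest_peak_cluster_selected(self, standard):
        v = gaussian_map(standard, (0.0, 30.0), amp=1.0) + gaussian_map(
            standard, (60.0, 90.0), amp=0.6
        )
        amap = AmplitudeMap(v, standard)
        labels = eg.segment_map(amap)
        primary = eg.select_primary_cluster(labels, amap)
        i_strong = int(np.argmin(np.linalg.norm(standard.positions - (0.0, 30.0), axis=1)))
        assert labels[i_strong] == primary

    def test_single_cluster_is_its_own_primary(self, standard):
        amap = AmplitudeMap(gaussian_map(standard, (30.0, 50.0)), standard)
        labels = eg.segment_map(amap)
        assert eg.select_primary_cluster(labels, amap) == labels[0]

    def test_exact_peak_tie_breaks_to_lowest_id(self):
        lay = eg.build_grid(eg.GridSpec(n_rows=1, n_cols=7, pitch_mm=10.0))
        v = np.array([1.0, 0.4, 0.1, 0.05, 0.1, 0.4, 1.0])  # two equal peaks
        amap = AmplitudeMap(v, lay)
        labels = eg.segment_map(amap)
        assert len(np.unique(labels)) == 2
        primary = eg.select_primary_cluster(labels, amap)
        assert primary == min(np.unique(labels))
        assert labels[0] == primary  # the left peak owns the primary label

    def test_threshold_is_strict_seventy_percent(self):
        lay = eg.build_grid(eg.GridSpec(n_rows=1, n_cols=3, pitch_mm=10.0))
        amap = AmplitudeMap(np.array([1.0, 0.8, 0.69]), lay)
        labels = np.ones(3, dtype=int)
        chans = eg.relevant_channels(amap, labels, 1)
        assert chans == ["r01c01", "r01c02"]
        # exactly 0.70 x max is excluded ("higher than" is strict)
        amap2 = AmplitudeMap(np.array([1.0, 0.8, 0.70]), lay)
        assert eg.relevant_channels(amap2, labels, 1) == ["r01c01", "r01c02"]

    def test_equal_amplitude_cluster_keeps_all_channels(self):
        lay = eg.build_grid(eg.GridSpec(n_rows=1, n_cols=4, pitch_mm=10.0))
        amap = AmplitudeMap(np.full(4, 0.5), lay)
        labels = np.ones(4, dtype=int)
        assert len(eg.relevant_channels(amap, labels, 1)) == 4

    def test_peak_channel_always_relevant(self, standard):
        rng = np.random.default_rng(12)
        amap = AmplitudeMap(rng.random(128) + 0.01, standard)
        labels = eg.segment_map(amap)
        primary = eg.select_primary_cluster(labels, amap)
        chans = eg.relevant_channels(amap, labels, primary)
        peak = standard.channels[int(np.argmax(amap.values))]
        assert peak in chans


class TestBarycenter:
    def test_single_channel_is_its_own_barycenter(self, standard):
        assert eg.barycenter(standard, ["r06c06"]) == standard.position("r06c06")

    def test_symmetric_pair_centers_on_reference(self, standard):
        ref = standard.spec.reference_col
        pair = [
            eg.grid.channel_id(6, ref - 1),
            eg.grid.channel_id(6, ref + 1),
        ]
        assert eg.barycenter(standard, pair)[0] == 0.0

    def test_matches_coordinate_mean_oracle(self, standard):
        rng = np.random.default_rng(4)
        chans = list(rng.choice(standard.channels, size=9, replace=False))
        b = eg.barycenter(standard, chans)
        pos = np.array([standard.position(c) for c in chans])
        assert b == pytest.approx(tuple(pos.sum(axis=0) / len(chans)))

    def test_empty_selection_errors(self, standard):
        with pytest.raises(EmptySelectionError):
            eg.barycenter(standard, [])

    def test_amplitude_weighting_shifts_toward_heavy_channel(self, standard):
        amap = AmplitudeMap(gaussian_map(standard, (45.0, 50.0)), standard)
        cfg = eg.SegmentationConfig(barycenter_weighting="amplitude")
        chans = ["r06c06", "r06c08"]  # x = 30 and 50; peak nearer 50
        bw = eg.barycenter(standard, chans, amap, cfg)
        assert 40.0 < bw[0] < 50.0


class TestNormalizeBarycenter:
    def test_cohort_mean_anatomy(self):
        X, Y = eg.normalize_barycenter((25.5, 50.4), 252.0, 255.0)
        assert X == pytest.approx(0.100)
        assert Y == pytest.approx(0.200)

    def test_origin_maps_to_origin(self):
        assert eg.normalize_barycenter((0.0, 0.0), 252.0, 255.0) == (0.0, 0.0)

    def test_doubling_anatomy_halves_coordinates(self):
        X1, Y1 = eg.normalize_barycenter((30.0, 60.0), 250.0, 260.0)
        X2, Y2 = eg.normalize_barycenter((30.0, 60.0), 500.0, 520.0)
        assert (X2, Y2) == (X1 / 2, Y1 / 2)

    def test_nonpositive_anatomy_rejected(self):
        with pytest.raises(InvalidMetadataError):
            eg.normalize_barycenter((1.0, 1.0), 0.0, 255.0)


class TestLocalize:
    def test_on_electrode_source_recovered_within_half_pitch(self, standard):
        center = standard.position("r07c07")
        rec = single_source_recording(standard, center=center, noise_rms=0.0)
        res = eg.localize(rec, standard)
        err = np.linalg.norm(np.array(res.barycenter_mm) - center)
        assert err <= 5.0

    def test_global_scaling_leaves_localization_unchanged(self, standard):
        rec = single_source_recording(standard, center=(33.0, 47.0), seed=21)
        res1 = eg.localize(rec, standard)
        scaled = eg.Recording(data=10.0 * rec.data, fs=rec.fs, meta=rec.meta)
        res2 = eg.localize(scaled, standard)
        assert res1.relevant_channels == res2.relevant_channels
        assert res1.barycenter_mm == res2.barycenter_mm
        assert np.array_equal(res1.labels, res2.labels)

    def test_stronger_of_two_sources_wins(self, standard):
        truth = eg.GroundTruth(
            sources=(
                eg.SourceSpec(center_mm=(10.0, 30.0), rms_amplitude=1.0),
                eg.SourceSpec(center_mm=(60.0, 80.0), rms_amplitude=0.5),
            ),
            noise_rms=0.05,
            seed=13,
        )
        rec = eg.generate_recording(standard, truth, 3.0, 2048.0)
        res = eg.localize(rec, standard)
        err = np.linalg.norm(np.array(res.barycenter_mm) - (10.0, 30.0))
        assert err <= 5.0

    def test_translation_covariance_one_pitch(self, standard):
        base = np.array([30.0, 50.0])
        for shift in (np.array([10.0, 0.0]), np.array([0.0, 10.0])):
            r1 = single_source_recording(standard, center=base, noise_rms=0.05, seed=17)
            r2 = single_source_recording(
                standard, center=base + shift, noise_rms=0.05, seed=17
            )
            b1 = np.array(eg.localize(r1, standard).barycenter_mm)
            b2 = np.array(eg.localize(r2, standard).barycenter_mm)
            assert np.linalg.norm((b2 - b1) - shift) <= 2.0

    def test_relevant_channels_subset_of_primary_cluster(self, standard):
        rec = single_source_recording(standard, center=(25.0, 60.0), seed=19)
        res = eg.localize(rec, standard)
        for ch in res.relevant_channels:
            assert res.labels[standard.index(ch)] == res.primary_cluster
        hull = standard.positions[
            [standard.index(c) for c in res.relevant_channels]
        ]
        assert hull[:, 0].min() <= res.barycenter_mm[0] <= hull[:, 0].max()
        assert hull[:, 1].min() <= res.barycenter_mm[1] <= hull[:, 1].max()

    def test_normalized_coordinates_require_anatomy(self, standard):
        rec = single_source_recording(standard, seed=1)
        assert eg.localize(rec, standard).barycenter_norm is None
        rec.meta.forearm_length_mm = 252.0
        rec.meta.forearm_circumference_mm = 255.0
        res = eg.localize(rec, standard)
        assert res.barycenter_norm == pytest.approx(
            (res.barycenter_mm[0] / 255.0, res.barycenter_mm[1] / 252.0)
        )

    def test_bad_channel_repair_recorded(self, standard):
        rec = single_source_recording(standard, seed=23)
        bad = eg.inject_bad_channels(rec, ["r10c10"], mode="flat", layout=standard)
        res = eg.localize(bad, standard)
        assert res.bad_channels == ["r10c10"]
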