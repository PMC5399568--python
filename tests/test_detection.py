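"""Peak-based nuclei detection: filter, maxima, merging, end to end."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from lobequant.detection import (
    DetectionParams,
    detect_nuclei,
    find_local_maxima,
    laplacian_filter,
    merge_across_planes,
)
from lobequant.metrics import precision_recall
from lobequant.reference import brute_force_local_maxima
from lobequant.stackio import ImageStack
from lobequant.synthesis import SynthesisParams, generate_lobe_image


def _blob(shape, centre, sd, amplitude=100.0):
    rr = np.arange(shape[0])[:, None] - centre[0]
    cc = np.arange(shape[1])[None, :] - centre[1]
    return amplitude * np.exp(-(rr**2 + cc**2) / (2 * sd * sd))


class TestLaplacianFilter:
    def test_constant_plane_maps_to_zero(self):
        resp = laplacian_filter(np.full((32, 32), 17.0), sigma=2.0)
        assert np.abs(resp).max() < 1e-9

    def test_blob_filtered_at_matched_scale_peaks_at_centre(self):
        plane = _blob((64, 64), (30, 25), sd=3.0)
        resp = laplacian_filter(plane, sigma=3.0)
        assert np.unravel_index(np.argmax(resp), resp.shape) == (30, 25)
        assert resp[30, 25] > 0  # bright blob becomes positive peak

    def test_linearity_for_far_apart_blobs(self):
        a = _blob((96, 96), (20, 20), sd=3.0)
        b = _blob((96, 96), (70, 70), sd=3.0)
        together = laplacian_filter(a + b, sigma=3.0)
        separate = laplacian_filter(a, sigma=3.0) + laplacian_filter(b, sigma=3.0)
        np.testing.assert_allclose(together, separate, atol=1e-6)

    def test_non_finite_input_rejected(self):
        plane = np.zeros((8, 8))
        plane[0, 0] = np.inf
        with pytest.raises(ValueError):
            laplacian_filter(plane, sigma=1.0)


class TestFindLocalMaxima:
    def test_single_positive_pixel_in_zero_field(self, det_params):
        resp = np.zeros((32, 32))
        resp[10, 20] = 5.0
        assert find_local_maxima(resp, det_params) == [(10, 20, 5.0)]

    def test_all_equal_response_yields_no_peaks(self, det_params):
        assert find_local_maxima(np.full((32, 32), 3.0), det_params) == []

    def test_equal_peaks_in_conflict_keep_smaller_row(self):
        params = DetectionParams(min_separation=12.0, abs_threshold_fraction=0.0)
        resp = np.zeros((40, 40))
        resp[12, 20] = 7.0
        resp[20, 20] = 7.0  # 8 px apart: strict maxima, but conflicting
        peaks = find_local_maxima(resp, params)
        assert peaks == [(12, 20, 7.0)]

    def test_sorted_by_descending_value(self, rng, det_params):
        resp = rng.random((64, 64))
        vals = [v for _, _, v in find_local_maxima(resp, det_params)]
        assert vals == sorted(vals, reverse=True)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        params = DetectionParams(
            min_separation=float(rng.integers(3, 13)),
            abs_threshold_fraction=float(rng.uniform(0.0, 0.5)),
        )
        resp = rng.normal(size=(48, 48))
        assert find_local_maxima(resp, params) == brute_force_local_maxima(resp, params)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        resp=hnp.arrays(
            dtype=np.float64,
            shape=st.tuples(st.integers(5, 20), st.integers(5, 20)),
            elements=st.floats(0, 100, allow_nan=False),
        ),
        min_sep=st.integers(2, 6),
    )
    def test_oracle_agreement_property(self, resp, min_sep):
        params = DetectionParams(min_separation=float(min_sep), abs_threshold_fraction=0.0)
        assert find_local_maxima(resp, params) == brute_force_local_maxima(resp, params)


class TestMergeAcrossPlanes:
    PEAKS = [(10, 10, 5.0), (30, 30, 4.0)]

    def test_identical_planes_collapse_to_single_plane_result(self):
        merged = merge_across_planes([self.PEAKS, self.PEAKS, self.PEAKS], merge_radius=6.0)
        assert len(merged) == 2
        assert {c.centre for c in merged} == {(10, 10), (30, 30)}

    def test_distant_peaks_on_different_planes_stay_separate(self):
        merged = merge_across_planes([[(5, 5, 3.0)], [(40, 40, 2.0)]], merge_radius=6.0)
        assert len(merged) == 2

    def test_jittered_duplicates_merge_keeping_strongest(self):
        planes = [[(10, 10, 5.0)], [(11, 10, 6.0)], [(10, 11, 4.0)]]
        merged = merge_across_planes(planes, merge_radius=6.0)
        assert len(merged) == 1
        (cell,) = merged
        assert cell.centre == (11, 10)
        assert cell.peak_response == 6.0
        assert cell.source_plane == 1

    def test_no_planes_rejected(self):
        with pytest.raises(ValueError):
            merge_across_planes([], merge_radius=6.0)


class TestDetectNuclei:
    def test_blank_stack_yields_no_cells(self, det_params):
        stack = ImageStack(np.zeros((2, 2, 64, 64)), ["DAPI", "RFP"])
        assert detect_nuclei(stack, det_params) == []

    def test_missing_nuclear_channel_is_an_error(self, det_params):
        stack = ImageStack(np.zeros((2, 2, 64, 64)), ["GFP", "RFP"])
        with pytest.raises(KeyError):
            detect_nuclei(stack, det_params)

    def test_noise_free_lobe_counts_exactly_with_subpixel_centres(
        self, small_lobe, det_params
    ):
        stack, truth = small_lobe
        cells = detect_nuclei(stack, det_params)
        assert len(cells) == len(truth.cells)
        rc = np.array([c.centre for c in cells], dtype=float)
        precision, recall, _ = precision_recall(rc, truth.centres_rc(), tolerance=1.0)
        assert precision == 1.0 and recall == 1.0

    def test_count_unchanged_when_planes_are_exact_copies(self, small_lobe, det_params):
        stack, _ = small_lobe
        one_plane = ImageStack(stack.pixels[:1].copy(), stack.channel_names)
        dup = ImageStack(
            np.repeat(stack.pixels[:1], 3, axis=0).copy(), stack.channel_names
        )
        cells_one = detect_nuclei(one_plane, det_params)
        cells_dup = detect_nuclei(dup, det_params)
        assert {c.centre for c in cells_dup} == {c.centre for c in cells_one}

    def test_translation_equivariance(self, det_params):
        params = SynthesisParams(
            image_height=160, image_width=160, n_nuclei=5, noise_sd=0.0, seed=3
        )
        stack, _ = generate_lobe_image(params)
        dr, dc = 7, 11
        shifted = np.roll(stack.pixels, (dr, dc), axis=(2, 3))
        cells = detect_nuclei(stack, det_params)
        cells_shifted = detect_nuclei(
            ImageStack(shifted, stack.channel_names), det_params
        )
        moved = {((r + dr) % 160, (c + dc) % 160) for r, c in (c.centre for c in cells)}
        assert {c.centre for c in cells_shifted} == moved

    def test_intensity_scale_invariance(self, noisy_lobe, det_params):
        stack, _ = noisy_lobe
        scaled = ImageStack(stack.pixels * 3.7, stack.channel_names)
        original = [(c.centre, c.source_plane) for c in detect_nuclei(stack, det_params)]
        rescaled = [(c.centre, c.source_plane) for c in detect_nuclei(scaled, det_params)]
        assert original == rescaled

    def test_high_accuracy_on_noisy_lobe(self, noisy_lobe, det_params):
        stack, truth = noisy_lobe
        cells = detect_nuclei(stack, det_params)
        rc = np.array([c.centre for c in cells], dtype=float)
        precision, recall, _ = precision_recall(rc, truth.centres_rc(), tolerance=6.0)
        assert precision >= 0.95
        assert recall >= 0.95


@pytest.mark.parametrize(
    "kwargs",
    [{"log_sigma": 0.0}, {"min_separation": 0.5}, {"merge_radius": 0.0},
     {"abs_threshold_fraction": 1.5}],
)
def test_invalid_detection_params_rejected(kwargs):
    with pytest.raises(ValueError):
        DetectionParams(**kwargs)
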