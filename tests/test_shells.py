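"""Shell geometry, reporter statistics, and the relative positivity rule."""

import numpy as np
import pytest

from lobequant.detection import DetectedCell, DetectionParams
from lobequant.shells import (
    LobeQuantification,
    ShellParams,
    classify_cells,
    full_shell_size,
    quantify_lobe,
    shell_mask,
    shell_statistic,
)
from lobequant.stackio import ImageStack
from lobequant.synthesis import SynthesisParams, generate_lobe_image


def _mask_set(mask):
    return set(zip(mask[0].tolist(), mask[1].tolist()))


class TestShellMask:
    def test_disc_of_radius_1p5_is_nine_pixels(self):
        """Pixels within Euclidean distance 1.5 of a central pixel are the
        pixel itself plus its 4 axial and 4 diagonal neighbours."""
        mask = shell_mask((10, 10), 0.0, 1.5, (21, 21))
        expected = {(10 + dr, 10 + dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)}
        assert _mask_set(mask) == expected

    def test_half_open_interval_excludes_outer_radius(self):
        mask = shell_mask((10, 10), 0.0, 1.0, (21, 21))
        assert _mask_set(mask) == {(10, 10)}  # axial neighbours at d=1 excluded

    def test_degenerate_radii_rejected(self):
        with pytest.raises(ValueError):
            shell_mask((5, 5), 2.0, 2.0, (11, 11))

    def test_corner_centre_is_clipped_not_an_error(self):
        mask = shell_mask((0, 0), 2.0, 5.0, (64, 64))
        rows, cols = mask
        assert len(rows) > 0
        assert (rows >= 0).all() and (cols >= 0).all()
        assert len(rows) < full_shell_size(2.0, 5.0)

    def test_default_geometry_never_samples_the_nucleus(self):
        """With gap = one nuclear diameter, every shell pixel is farther
        than the nuclear radius from the peak."""
        p = ShellParams()
        rows, cols = shell_mask((50, 50), p.gap, p.gap + p.shell_width, (101, 101))
        d = np.sqrt((rows - 50.0) ** 2 + (cols - 50.0) ** 2)
        assert d.min() >= 12.0  # nuclear radius would be 6

    def test_mask_matches_brute_force_distance_enumeration(self):
        inner, outer, centre = 3.0, 7.5, (12, 20)
        mask = shell_mask(centre, inner, outer, (30, 40))
        brute = {
            (r, c)
            for r in range(30)
            for c in range(40)
            if inner <= np.hypot(r - centre[0], c - centre[1]) < outer
        }
        assert _mask_set(mask) == brute


class TestShellStatistic:
    def test_uniform_plane_mean_is_value(self):
        plane = np.full((20, 20), 4.5)
        mask = shell_mask((10, 10), 2.0, 5.0, plane.shape)
        assert shell_statistic(plane, mask, "mean") == pytest.approx(4.5)

    def test_statistic_sees_only_masked_pixels(self):
        plane = np.zeros((30, 30))
        mask = shell_mask((15, 15), 3.0, 6.0, plane.shape)
        plane[mask] = 10.0
        plane[0, 0] = 1e6  # far outside the shell
        assert shell_statistic(plane, mask, "mean") == pytest.approx(10.0)
        assert shell_statistic(plane, mask, "median") == pytest.approx(10.0)
        assert shell_statistic(plane, mask, "max") == pytest.approx(10.0)

    def test_empty_mask_returns_zero(self):
        empty = (np.empty(0, dtype=int), np.empty(0, dtype=int))
        assert shell_statistic(np.ones((5, 5)), empty, "mean") == 0.0

    def test_unknown_statistic_rejected(self):
        mask = shell_mask((2, 2), 0.0, 1.5, (5, 5))
        with pytest.raises(ValueError):
            shell_statistic(np.ones((5, 5)), mask, "mode")

    def test_shell_aligned_with_ring_reads_ring_plus_background(self):
        """Noise-free positive cell: the shell (same radii as the ring)
        reads exactly ring intensity + background."""
        params = SynthesisParams(
            image_height=96, image_width=96, n_nuclei=1,
            positive_fraction=1.0, noise_sd=0.0, seed=5,
        )
        stack, truth = generate_lobe_image(params)
        cell = truth.cells[0]
        projection = stack.channel("RFP").max(axis=0)
        mask = shell_mask((cell.y, cell.x), 12.0, 18.0, projection.shape)
        value = shell_statistic(projection, mask, "mean")
        assert value == pytest.approx(
            params.reporter_ring_intensity + params.background_level, abs=1e-9
        )


def _manual_stack(shell_values, shape=(200, 200), params=None):
    """Stack with cells whose raw shell means are exactly `shell_values`
    (background 0, one ring-filled shell per cell)."""
    params = params or ShellParams(background_correction="none")
    reporter = np.zeros(shape)
    cells = []
    spacing = 48
    for i, v in enumerate(shell_values):
        r, cpos = 30 + spacing * (i // 3), 30 + spacing * (i % 3)
        mask = shell_mask((r, cpos), params.gap, params.gap + params.shell_width, shape)
        reporter[mask] = v
        cells.append(DetectedCell(centre=(r, cpos), source_plane=0, peak_response=1.0))
    pixels = np.stack([np.zeros(shape), reporter])[None]
    return ImageStack(pixels, ["DAPI", "RFP"]), cells, params


class TestClassifyCells:
    def test_cell_at_the_maximum_is_always_positive(self):
        stack, cells, params = _manual_stack([10.0, 100.0, 40.0])
        out = classify_cells(cells, stack, params)
        assert out[1].is_positive is True

    def test_value_just_below_threshold_is_negative(self):
        stack, cells, params = _manual_stack([74.0, 100.0])
        out = classify_cells(cells, stack, params)
        assert [c.is_positive for c in out] == [False, True]
        stack2, cells2, params2 = _manual_stack([75.0, 100.0])
        assert classify_cells(cells2, stack2, params2)[0].is_positive is True

    def test_all_zero_shell_values_mean_all_negative(self):
        stack, cells, params = _manual_stack([0.0, 0.0, 0.0])
        out = classify_cells(cells, stack, params)
        assert all(c.is_positive is False for c in out)

    def test_positive_rescaling_leaves_classification_unchanged(self):
        stack, cells, _ = _manual_stack([10, 20, 74, 76, 100.0])
        params = ShellParams()  # default background correction
        baseline = [c.is_positive for c in classify_cells(cells, stack, params)]
        for scale in (0.01, 3.0, 1000.0):
            scaled = ImageStack(stack.pixels * scale, stack.channel_names)
            stack_s, cells_s, _ = _manual_stack([10, 20, 74, 76, 100.0])
            out = [
                c.is_positive
                for c in classify_cells(cells_s, scaled, params)
            ]
            assert out == baseline

    def test_raising_threshold_never_adds_positives(self):
        values = [5, 30, 60, 74, 76, 90, 100.0]
        counts = []
        for frac in (0.0, 0.25, 0.5, 0.75, 0.9, 1.0):
            stack, cells, _ = _manual_stack(values)
            params = ShellParams(threshold_fraction=frac, background_correction="none")
            out = classify_cells(cells, stack, params)
            counts.append(sum(c.is_positive for c in out))
        assert counts == sorted(counts, reverse=True)
        assert counts[0] == len(values)  # threshold 0: everything positive
        assert counts[-1] == 1  # threshold 1: only the maximum

    def test_missing_reporter_channel_is_an_error(self):
        stack = ImageStack(np.zeros((1, 2, 64, 64)), ["DAPI", "GFP"])
        cell = DetectedCell(centre=(32, 32), source_plane=0, peak_response=1.0)
        with pytest.raises(KeyError):
            classify_cells([cell], stack, ShellParams())

    def test_border_cells_flagged_and_excluded_from_threshold(self):
        """A bright border cell with a heavily clipped shell must not
        define the lobe threshold, but is itself still classified."""
        shape = (200, 200)
        params = ShellParams(background_correction="none")
        reporter = np.zeros(shape)
        interior = DetectedCell(centre=(100, 100), source_plane=0, peak_response=1.0)
        border = DetectedCell(centre=(0, 0), source_plane=0, peak_response=1.0)
        m_int = shell_mask((100, 100), params.gap, params.gap + params.shell_width, shape)
        m_bor = shell_mask((0, 0), params.gap, params.gap + params.shell_width, shape)
        reporter[m_int] = 50.0
        reporter[m_bor] = 1000.0
        stack = ImageStack(np.stack([np.zeros(shape), reporter])[None], ["DAPI", "RFP"])
        out = classify_cells([interior, border], stack, params)
        assert out[1].border_clipped is True
        assert out[0].border_clipped is False
        # threshold comes from the interior cell (50), not the border cell
        assert out[0].is_positive is True
        assert out[1].is_positive is True  # still classified (1000 >= 37.5)


class TestQuantifyLobe:
    def test_blank_stack_has_missing_percentage(self, det_params, shell_params):
        stack = ImageStack(np.zeros((2, 2, 64, 64)), ["DAPI", "RFP"], lobe_id="blank")
        q = quantify_lobe(stack, det_params, shell_params)
        assert q.n_cells == 0
        assert q.percent_positive is None

    def test_noise_free_lobe_recovers_exact_positive_fraction(
        self, det_params, shell_params
    ):
        params = SynthesisParams(noise_sd=0.0, positive_fraction=0.5, seed=21)
        stack, _ = generate_lobe_image(params, lobe_id="clean")
        q = quantify_lobe(stack, det_params, shell_params)
        assert q.n_cells == 100
        assert q.percent_positive == pytest.approx(50.0)


class TestLobeQuantification:
    def test_percent_must_match_counts(self):
        with pytest.raises(ValueError):
            LobeQuantification("x", "g", 10, 5, 99.0)
        with pytest.raises(ValueError):
            LobeQuantification("x", "g", 10, 11, 110.0)
        with pytest.raises(ValueError):
            LobeQuantification("x", "g", 0, 0, 0.0)  # must be missing

    def test_from_counts(self):
        q = LobeQuantification.from_counts("x", "g", 8, 2)
        assert q.percent_positive == pytest.approx(25.0)


@pytest.mark.parametrize(
    "kwargs",
    [{"gap": -1.0}, {"shell_width": 0.5}, {"threshold_fraction": 1.5},
     {"shell_statistic": "mode"}, {"threshold_scope": "galaxy"},
     {"background_correction": "local"}],
)
def test_invalid_shell_params_rejected(kwargs):
    with pytest.raises(ValueError):
        ShellParams(**kwargs)
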