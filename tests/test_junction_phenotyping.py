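import numpy as np
import pytest

from junctionlab import (
    CONTINUOUS,
    PERPENDICULAR,
    PHENOTYPES,
    PUNCTATE,
    BinaryMask,
    ConfigError,
    IntensityImage,
    JunctionPiece,
    classify_junction_piece,
    compute_cell_coverage,
    extract_junction_pieces,
    isolate_junction_mask,
)
from oracles import chebyshev_covered_indices, flood_fill_components


class TestIsolateJunctionMask:
    def test_subthreshold_uniform_is_empty(self):
        img = IntensityImage(np.full((32, 32), 4, np.uint8), 8,
                             channel_label="VE-cadherin")
        assert isolate_junction_mask(img).count() == 0

    def test_zo1_default_threshold_keeps_blob(self):
        arr = np.zeros((64, 64), np.uint8)
        arr[10:20, 10:20] = 20  # 100-px blob above the ZO-1 default of 15
        img = IntensityImage(arr, 8, channel_label="ZO-1")
        assert isolate_junction_mask(img).count() == 100

    def test_unknown_label_without_threshold(self):
        img = IntensityImage(np.zeros((8, 8), np.uint8), 8, channel_label="occludin")
        with pytest.raises(ConfigError):
            isolate_junction_mask(img)
        assert isolate_junction_mask(img, threshold=10).count() == 0

    def test_no_smoothing_matches_per_pixel_loop(self):
        rng = np.random.default_rng(11)
        arr = rng.integers(0, 40, (21, 23), dtype=np.uint8)
        mask = isolate_junction_mask(IntensityImage(arr, 8), threshold=15)
        for r in range(21):
            for c in range(23):
                assert mask.pixels[r, c] == (arr[r, c] >= 15)

    def test_smoothing_spreads_signal(self):
        arr = np.zeros((33, 33), np.uint8)
        arr[16, 16] = 255
        img = IntensityImage(arr, 8)
        raw = isolate_junction_mask(img, threshold=5)
        smoothed = isolate_junction_mask(img, threshold=5, smooth_sigma=1.5)
        assert smoothed.count() > raw.count()


class TestExtractJunctionPieces:
    def test_empty_mask(self, rect_path):
        _, path = rect_path
        mask = BinaryMask(np.zeros((240, 240), dtype=bool))
        assert extract_junction_pieces(mask, path) == []

    def test_component_on_path_covers_expected_stretch(self, rect_path):
        _, path = rect_path
        arr = np.zeros((240, 240), dtype=bool)
        arr[0, 50:70] = True  # 20 px along the top edge, on the path itself
        pieces = extract_junction_pieces(BinaryMask(arr), path, corridor_radius=1)
        assert len(pieces) == 1
        # covered stretch spills one path pixel past each end of the run
        assert pieces[0].l_path == 22

    def test_far_component_excluded(self, rect_path):
        _, path = rect_path
        arr = np.zeros((240, 240), dtype=bool)
        arr[100:110, 100:110] = True  # deep interior, >= 2 px from any path pixel
        assert extract_junction_pieces(BinaryMask(arr), path, corridor_radius=1) == []

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_flood_fill_distance_oracle(self, seed, rect_path):
        _, big_path = rect_path
        rng = np.random.default_rng(seed)
        arr = rng.random((64, 64)) < 0.12
        from junctionlab import WaypointTrace, build_cell_path

        trace = WaypointTrace("t", np.array([(8, 8), (8, 55), (55, 55), (55, 8)]))
        path = build_cell_path(trace, (64, 64))
        pieces = extract_junction_pieces(BinaryMask(arr), path, corridor_radius=1)
        got = {frozenset(map(tuple, p.pixel_set)): frozenset(p.covered_path_pixels.tolist())
               for p in pieces}
        expected = {}
        for comp in flood_fill_components(arr):
            covered = chebyshev_covered_indices(comp, path.path_pixels, 1)
            if covered:
                expected[comp] = covered
        assert got == expected


def _piece_with(path, start, l_path, width=1, height=1):
    """A synthetic piece covering `l_path` top-edge path pixels, whose pixel
    set is a free-standing width x height rectangle (tangential x normal)."""
    idxs = np.arange(start, start + l_path)
    rows, cols = np.mgrid[100:100 + height, 100:100 + width]
    return JunctionPiece(piece_id=1,
                         pixel_set=np.column_stack([rows.ravel(), cols.ravel()]),
                         covered_path_pixels=idxs)


class TestClassificationBoundaries:
    """The phenotype rules are strict: > 15 path px for continuous and
    > 1.2 normal/tangential aspect for perpendicular."""

    @pytest.mark.parametrize("l_path,expected", [
        (14, PUNCTATE), (15, PUNCTATE), (16, CONTINUOUS), (30, CONTINUOUS),
    ])
    def test_path_length_boundary(self, rect_path, l_path, expected):
        _, path = rect_path
        piece = _piece_with(path, 10, l_path, width=l_path, height=1)
        assert classify_junction_piece(piece, path) == expected

    @pytest.mark.parametrize("height,expected", [
        (119, PUNCTATE),        # aspect 1.19
        (120, PUNCTATE),        # aspect 1.20 exactly: strict, stays punctate
        (121, PERPENDICULAR),   # aspect 1.21
    ])
    def test_aspect_ratio_boundary(self, rect_path, height, expected):
        _, path = rect_path
        piece = _piece_with(path, 10, 5, width=100, height=height)
        assert classify_junction_piece(piece, path) == expected
        assert piece.aspect_ratio == pytest.approx(height / 100)

    def test_perpendicular_bar_example(self, rect_path):
        _, path = rect_path
        piece = _piece_with(path, 10, 8, width=3, height=9)  # aspect 3.0
        assert classify_junction_piece(piece, path) == PERPENDICULAR
        assert piece.aspect_ratio == pytest.approx(3.0)

    def test_single_covered_pixel_uses_neighbour_tangent(self, rect_path):
        _, path = rect_path
        piece = _piece_with(path, 50, 1, width=1, height=5)
        assert classify_junction_piece(piece, path) == PERPENDICULAR


class TestCellCoverage:
    def test_no_pieces_is_all_none(self, rect_path):
        _, path = rect_path
        cov = compute_cell_coverage([], path)
        assert cov.pct_total == 0
        assert cov.pct_none == 100

    def test_full_continuous_coverage(self, rect_path):
        _, path = rect_path
        piece = JunctionPiece(piece_id=1, pixel_set=path.path_pixels.copy(),
                              covered_path_pixels=np.arange(path.path_length_px))
        cov = compute_cell_coverage([piece], path)
        assert cov.pct_continuous == 100.0
        assert cov.pct_none == 0.0
        assert cov.counts[CONTINUOUS] == 1

    def test_contested_pixel_goes_to_nearest_piece(self, rect_path):
        _, path = rect_path
        near = JunctionPiece(1, pixel_set=np.array([[1, 60]]),
                             covered_path_pixels=np.array([60]))
        far = JunctionPiece(2, pixel_set=np.array([[2, 60], [2, 61]]),
                            covered_path_pixels=np.array([60, 61]))
        cov = compute_cell_coverage([near, far], path)
        assert cov.piece_assignment[60] == 1  # Chebyshev 1 beats Chebyshev 2
        assert cov.piece_assignment[61] == 2

    def test_tie_broken_toward_larger_piece(self, rect_path):
        _, path = rect_path
        small = JunctionPiece(1, pixel_set=np.array([[1, 60]]),
                              covered_path_pixels=np.array([60]))
        large = JunctionPiece(2, pixel_set=np.array([[1, 61], [1, 62], [2, 61]]),
                              covered_path_pixels=np.array([60, 61, 62]))
        cov = compute_cell_coverage([small, large], path)
        assert cov.piece_assignment[60] == 2

    def test_conservation_on_synthetic_cells(self, monolayer):
        from junctionlab import compute_cell_coverage as ccc

        mask = isolate_junction_mask(monolayer.junction_image, threshold=15)
        for cid, path in monolayer.truth.paths.items():
            pieces = extract_junction_pieces(mask, path, 1)
            cov = ccc(pieces, path)
            total = (cov.pct_continuous + cov.pct_punctate
                     + cov.pct_perpendicular + cov.pct_none)
            assert total == pytest.approx(100.0, abs=0.01)
            assert cov.pct_discontinuous == pytest.approx(
                cov.pct_punctate + cov.pct_perpendicular, abs=1e-9)

    def test_total_coverage_monotone_in_threshold(self, monolayer):
        from junctionlab import NoiseModel, generate_monolayer

        noisy = generate_monolayer(n_cells=8, image_size=256, seed=2,
                                   noise=NoiseModel(background_mean=10,
                                                    background_sd=12))
        path = next(iter(noisy.truth.paths.values()))
        totals = []
        for threshold in (12, 25, 60, 150):
            mask = isolate_junction_mask(noisy.junction_image, threshold=threshold)
            cov = compute_cell_coverage(
                extract_junction_pieces(mask, path, 1), path)
            totals.append(cov.pct_total)
        assert all(a >= b for a, b in zip(totals, totals[1:]))
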