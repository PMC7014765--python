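import numpy as np
import pytest

from junctionlab import (
    BinaryMask,
    IntensityImage,
    ShapeError,
    TracedCell,
    WaypointTrace,
    build_cell_path,
    categorize_pr,
    compute_cell_coverage,
    compute_colocalization,
    detect_permeated_regions,
    extract_junction_pieces,
    isolate_junction_mask,
    profile_pr_path,
    summarize_prs,
)
from junctionlab.local_permeability import PermeatedRegion
from oracles import union_find_components


def _img(arr):
    return IntensityImage(arr.astype(np.uint8), 8, channel_label="avidin")


def _two_cell_scene():
    """Two 60x118 rectangular cells sharing the border row 60, columns 1-118,
    in a 128x128 field.  Returns (cells, shape)."""
    shape = (128, 128)
    top = WaypointTrace("top", np.array([(1, 1), (1, 118), (60, 118), (60, 1)]))
    bottom = WaypointTrace("bottom", np.array([(60, 1), (60, 118), (120, 118), (120, 1)]))
    cells = []
    for tr in (top, bottom):
        path = build_cell_path(tr, shape)
        cells.append(TracedCell.from_trace(tr, path))
    return cells, shape


class TestDetectPermeatedRegions:
    def test_zero_image(self):
        assert detect_permeated_regions(_img(np.zeros((32, 32)))) == []

    def test_single_block_area(self):
        arr = np.zeros((64, 64))
        arr[10:40, 10:40] = 255
        prs = detect_permeated_regions(_img(arr))
        assert len(prs) == 1
        assert prs[0].area_px2 == 900

    def test_16bit_input_converted_first(self):
        arr = np.zeros((32, 32), np.uint16)
        arr[5:10, 5:10] = 65535  # maps to 255 after min-max rescale
        prs = detect_permeated_regions(IntensityImage(arr, 16))
        assert len(prs) == 1 and prs[0].area_px2 == 25

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_union_find_oracle(self, seed):
        rng = np.random.default_rng(seed)
        arr = np.where(rng.random((64, 64)) < 0.2, 255, 0)
        prs = detect_permeated_regions(_img(arr))
        got = {frozenset(map(tuple, pr.pixel_set)) for pr in prs}
        expected = set(union_find_components(arr >= 240))
        assert got == expected


class TestCategorizePr:
    def test_interior_pr_is_uni(self):
        cells, shape = _two_cell_scene()
        px = np.column_stack(np.mgrid[20:30, 40:50]).reshape(-1, 2)
        px = np.column_stack(np.nonzero(_block(shape, 20, 30, 40, 50)))
        pr = PermeatedRegion(1, px, shape)
        pr = categorize_pr(pr, cells, adjacency_radius=2)
        assert pr.category == "Uni"
        assert pr.associated_cell_ids == frozenset({"top"})

    def test_border_pr_is_bi(self):
        cells, shape = _two_cell_scene()
        pr = PermeatedRegion(1, np.column_stack(np.nonzero(_block(shape, 50, 70, 40, 60))),
                             shape)
        pr = categorize_pr(pr, cells, adjacency_radius=2)
        assert pr.category == "Bi"
        assert pr.associated_cell_ids == frozenset({"top", "bottom"})

    def test_no_cell_is_unassigned(self):
        cells, shape = _two_cell_scene()
        pr = PermeatedRegion(1, np.array([[126, 126]]), shape)
        assert categorize_pr(pr, cells).category == "Unassigned"

    def test_six_cells_is_multi(self, monolayer):
        # a blob spanning the whole field touches every traced cell
        shape = (monolayer.truth.image_size,) * 2
        cells = [TracedCell.from_trace(monolayer.traces[cid],
                                       monolayer.truth.paths[cid])
                 for cid in sorted(monolayer.traces)]
        rows, cols = np.mgrid[0:shape[0]:8, 0:shape[1]:8]
        pr = PermeatedRegion(1, np.column_stack([rows.ravel(), cols.ravel()]), shape)
        pr = categorize_pr(pr, cells)
        assert len(pr.associated_cell_ids) >= 5
        assert pr.category == "Multi"


class TestProfilePrPath:
    def _profiled(self, area_side_px):
        cells, shape = _two_cell_scene()
        junction = np.zeros(shape, np.uint8)
        junction[60, 30:90] = 200  # continuous run on the shared border
        mask = isolate_junction_mask(IntensityImage(junction, 8), threshold=15)
        covs = {}
        for cell in cells:
            pieces = extract_junction_pieces(mask, cell.path, 1)
            covs[cell.cell_id] = compute_cell_coverage(pieces, cell.path)
        block = _block(shape, 61 - area_side_px // 2, 61 + (area_side_px + 1) // 2,
                       40, 40 + area_side_px)
        pr = PermeatedRegion(1, np.column_stack(np.nonzero(block)), shape)
        pr = categorize_pr(pr, cells)
        return profile_pr_path(pr, cells, covs)

    def test_area_exactly_400_excluded(self):
        assert self._profiled(20) is None  # 20x20 = 400 px^2

    def test_area_401_included(self):
        cells, shape = _two_cell_scene()
        block = _block(shape, 50, 70, 40, 60)
        px = np.column_stack(np.nonzero(block))
        pr = PermeatedRegion(1, px, shape)
        pr = categorize_pr(pr, cells)
        covs = {c.cell_id: compute_cell_coverage([], c.path) for c in cells}
        assert pr.area_px2 == 400
        assert profile_pr_path(pr, cells, covs) is None
        bigger = np.vstack([px, [[50, 61]]])
        pr2 = categorize_pr(PermeatedRegion(2, bigger, shape), cells)
        assert pr2.area_px2 == 401
        assert profile_pr_path(pr2, cells, covs) is not None

    def test_fully_continuous_pr_path(self):
        prof = self._profiled(30)
        assert prof is not None
        assert prof.pct("continuous") == 100.0
        assert prof.no_junction_length == 0
        assert prof.phenotype_counts["continuous"] == 2  # once per bordering cell

    def test_length_conservation(self, monolayer):
        from junctionlab import generate_pr_overlay, make_pr_plan

        plan = make_pr_plan(monolayer.truth, n_uni=2, n_bi=3, n_tri=1, seed=9)
        avidin, _ = generate_pr_overlay(monolayer.truth, plan, seed=10)
        mask = isolate_junction_mask(monolayer.junction_image, threshold=15)
        cells = [TracedCell.from_trace(monolayer.traces[cid],
                                       monolayer.truth.paths[cid])
                 for cid in sorted(monolayer.traces)]
        covs = {c.cell_id: compute_cell_coverage(
            extract_junction_pieces(mask, c.path, 1), c.path) for c in cells}
        profiled = 0
        for pr in detect_permeated_regions(avidin):
            pr = categorize_pr(pr, cells)
            prof = profile_pr_path(pr, cells, covs)
            if prof is None:
                continue
            profiled += 1
            total = sum(prof.phenotype_lengths.values()) + prof.no_junction_length
            assert total == prof.pr_path_length
            if prof.pr_path_length > 0:  # deep-interior Uni PRs touch no path
                pcts = sum(prof.pct(ph) for ph in prof.phenotype_lengths) \
                    + prof.pct("none")
                assert pcts == pytest.approx(100.0, abs=0.01)
        assert profiled >= 1


class TestColocalization:
    def _mask(self, shape, sl=None):
        arr = np.zeros(shape, dtype=bool)
        if sl is not None:
            arr[sl] = True
        return BinaryMask(arr)

    def test_identities(self):
        shape = (64, 64)
        pr = self._mask(shape, np.s_[0:32, :])
        disjoint = self._mask(shape, np.s_[45:55, 30:50])
        nested = self._mask(shape, np.s_[5:15, 5:15])
        half = self._mask(shape, np.s_[22:42, 0:10])  # 100 of 200 px inside
        res = {r.phenotype: r for r in compute_colocalization(
            {"disjoint": disjoint, "nested": nested, "half": half}, pr)}
        assert res["disjoint"].pct_colocalization == 0.0
        assert res["nested"].pct_colocalization == 100.0
        assert res["half"].a_total == 200 and res["half"].a_pr == 100
        assert res["half"].pct_colocalization == 50.0

    def test_absent_phenotype_undefined(self):
        shape = (16, 16)
        res = compute_colocalization({"empty": self._mask(shape)},
                                     self._mask(shape, np.s_[0:8, :]))
        assert res[0].pct_colocalization is None

    def test_shape_mismatch(self):
        with pytest.raises(ShapeError):
            compute_colocalization({"a": self._mask((8, 8))}, self._mask((9, 9)))

    def test_overlapping_phenotype_masks_rejected(self):
        shape = (16, 16)
        a = self._mask(shape, np.s_[0:8, :])
        b = self._mask(shape, np.s_[4:12, :])
        with pytest.raises(ShapeError):
            compute_colocalization({"a": a, "b": b}, self._mask(shape))


class TestSummarizePrs:
    def _pr(self, pr_id, area, category):
        px = np.zeros((area, 2), dtype=np.int64)
        px[:, 1] = np.arange(area)
        px[:, 0] = pr_id
        return PermeatedRegion(pr_id, px, (600, 600), frozenset({"c"}), category)

    def test_single_image_counts(self):
        counts, areas = summarize_prs(
            {"img1": [self._pr(1, 500, "Bi"), self._pr(2, 450, "Bi"),
                      self._pr(3, 100, "Uni")]})
        row = counts.iloc[0]
        assert row["Uni"] == 1 and row["Bi"] == 2
        assert row["Tri"] == row["Quad"] == row["Multi"] == 0

    def test_identical_images_average_to_single_image_count(self):
        prs = [self._pr(1, 500, "Bi"), self._pr(2, 100, "Uni")]
        counts, _ = summarize_prs({"a": prs, "b": prs})
        assert counts["Bi"].mean() == 1.0
        assert counts["Uni"].mean() == 1.0

    def test_means_match_accumulation_loop(self):
        rng = np.random.default_rng(4)
        cats = ["Uni", "Bi", "Tri", "Quad", "Multi"]
        prs_by_image = {}
        acc = {c: [] for c in cats}
        for i in range(4):
            prs = []
            for j in range(rng.integers(2, 7)):
                cat = cats[rng.integers(0, 5)]
                area = int(rng.integers(50, 2000))
                prs.append(self._pr(j + 1, area, cat))
                acc[cat].append(area)
            prs_by_image[f"img{i}"] = prs
        _, areas = summarize_prs(prs_by_image)
        for cat in cats:
            row = areas[areas.category == cat].iloc[0]
            if acc[cat]:
                assert row["n"] == len(acc[cat])
                assert row["mean_area_px2"] == pytest.approx(
                    sum(acc[cat]) / len(acc[cat]))
            else:
                assert row["n"] == 0

    def test_unassigned_excluded(self):
        counts, areas = summarize_prs({"i": [self._pr(1, 50, "Unassigned")]})
        assert counts.iloc[0][["Uni", "Bi", "Tri", "Quad", "Multi"]].sum() == 0
        assert areas["n"].sum() == 0


def _block(shape, r0, r1, c0, c1):
    arr = np.zeros(shape, dtype=bool)
    arr[r0:r1, c0:c1] = True
    return arr
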