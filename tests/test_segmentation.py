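import numpy as np
import networkx as nx
import pytest

from octpath import (
    AnchorPoint,
    InfeasiblePathError,
    SegmentationOrderingError,
    ValidationError,
    negate_image,
    normalize_intensity,
    segment_all,
    segment_ilm,
    segment_isos,
    segment_rpe_center,
    segment_rpe_outer,
    shortest_path,
    vertical_gradient,
)
from octpath.core_io import BScan, Calibration
from octpath.segmentation import (
    CostImage,
    LayerSegmentation,
    SearchBand,
    SegmentationConfig,
    estimate_rpe_row,
)
from octpath.phantom import device_a_spec, generate_phantom


class TestCostConstructions:
    def test_negate_arithmetic_and_involution(self, rng):
        img = rng.random((6, 5))
        cost = negate_image(img)
        np.testing.assert_allclose(cost.values, 1.0 - img)
        np.testing.assert_allclose(1.0 - cost.values, img)
        assert negate_image(np.ones((2, 2))).values.max() == 0.0

    def test_negate_rejects_out_of_range(self):
        with pytest.raises(ValidationError):
            negate_image(np.array([[0.5, 1.5]]))

    def test_gradient_single_edge_polarity(self):
        col = np.array([[0.0], [0.0], [1.0], [1.0]])
        d2b = vertical_gradient(col, "dark_to_bright").values
        assert d2b.argmin() == 1  # forward difference fires at the last dark row
        b2d = vertical_gradient(col, "bright_to_dark").values
        np.testing.assert_allclose(b2d, 1.0)  # no matching edge anywhere

    def test_gradient_two_edges(self):
        # column [0,1,1,0]: rising edge at row 0, falling edge at row 2
        col = np.array([[0.0], [1.0], [1.0], [0.0]])
        assert vertical_gradient(col, "dark_to_bright").values.argmin() == 0
        assert vertical_gradient(col, "bright_to_dark").values.argmin() == 2

    def test_gradient_needs_two_rows(self):
        with pytest.raises(ValidationError):
            vertical_gradient(np.ones((1, 4)), "dark_to_bright")
        with pytest.raises(ValidationError):
            vertical_gradient(np.ones((4, 4)), "sideways")


def _oracle(cost, band, max_jump):
    """Independent node-weighted DAG shortest path via Dijkstra."""
    n_rows, n_cols = cost.shape
    G = nx.DiGraph()
    for c in range(n_cols):
        for r in range(band.lower[c], band.upper[c] + 1):
            if c == 0:
                G.add_edge("s", (r, 0), weight=cost[r, 0])
            if c == n_cols - 1:
                G.add_edge((r, c), "t", weight=0.0)
            if c < n_cols - 1:
                lo = max(band.lower[c + 1], r - max_jump)
                hi = min(band.upper[c + 1], r + max_jump)
                for r2 in range(lo, hi + 1):
                    G.add_edge((r, c), (r2, c + 1), weight=cost[r2, c + 1])
    length = nx.dijkstra_path_length(G, "s", "t")
    path = nx.dijkstra_path(G, "s", "t")[1:-1]
    return length, np.array([r for r, _ in path])


class TestShortestPath:
    def test_diagonal_example(self):
        cost = np.array([[1, 9, 9], [9, 1, 9], [9, 9, 1]], dtype=float)
        bp = shortest_path(CostImage(cost), SearchBand.full(3, 3), max_jump=1)
        np.testing.assert_array_equal(bp.rows, [0, 1, 2])
        assert bp.cost == 3.0

    def test_tie_break_to_smallest_row(self):
        bp = shortest_path(CostImage(np.zeros((4, 6))), SearchBand.full(4, 6), 1)
        np.testing.assert_array_equal(bp.rows, 0)
        assert bp.cost == 0.0

    def test_continuity_bound_holds(self, rng):
        cost = rng.random((12, 30))
        for mj in (1, 2, 3):
            bp = shortest_path(CostImage(cost), SearchBand.full(12, 30), mj)
            assert np.all(np.abs(np.diff(bp.rows)) <= mj)

    def test_matches_dijkstra_oracle(self, rng):
        for _ in range(100):
            n_rows = int(rng.integers(3, 21))
            n_cols = int(rng.integers(2, 26))
            mj = int(rng.integers(1, 4))
            cost = rng.random((n_rows, n_cols))
            band = SearchBand.full(n_rows, n_cols)
            bp = shortest_path(CostImage(cost), band, mj)
            oracle_cost, oracle_rows = _oracle(cost, band, mj)
            assert bp.cost == pytest.approx(oracle_cost, abs=1e-12)
            # continuous costs: the optimum is almost surely unique
            np.testing.assert_array_equal(bp.rows, oracle_rows)

    def test_banded_matches_oracle(self, rng):
        for _ in range(20):
            n_rows, n_cols = 15, 12
            # band edges drift slowly so adjacent columns stay reachable
            steps = rng.integers(-2, 3, size=n_cols)
            lower = np.clip(4 + np.cumsum(steps), 0, 8)
            upper = lower + rng.integers(3, 7, size=n_cols)
            band = SearchBand(lower, np.minimum(upper, n_rows - 1))
            cost = rng.random((n_rows, n_cols))
            bp = shortest_path(CostImage(cost), band, 3)
            oracle_cost, _ = _oracle(cost, band, 3)
            assert bp.cost == pytest.approx(oracle_cost, abs=1e-12)
            assert np.all(bp.rows >= band.lower) and np.all(bp.rows <= band.upper)

    def test_anchor_forces_passage(self):
        bp = shortest_path(
            CostImage(np.zeros((5, 5))), SearchBand.full(5, 5), 2,
            anchors=[AnchorPoint(column=2, row=4)],
        )
        assert bp.rows[2] == 4

    def test_anchor_on_optimal_path_is_noop(self):
        cost = np.array([[1, 9, 9], [9, 1, 9], [9, 9, 1]], dtype=float)
        free = shortest_path(CostImage(cost), SearchBand.full(3, 3), 1)
        anchored = shortest_path(
            CostImage(cost), SearchBand.full(3, 3), 1,
            anchors=[AnchorPoint(column=1, row=1)],
        )
        np.testing.assert_array_equal(free.rows, anchored.rows)
        assert free.cost == anchored.cost

    def test_constrained_cost_never_below_unconstrained(self, rng):
        for _ in range(20):
            cost = rng.random((10, 15))
            full = SearchBand.full(10, 15)
            free = shortest_path(CostImage(cost), full, 2)
            col = int(rng.integers(0, 15))
            row = int(rng.integers(0, 10))
            try:
                anchored = shortest_path(
                    CostImage(cost), full, 2, anchors=[AnchorPoint(col, row)]
                )
            except InfeasiblePathError:
                continue
            assert anchored.cost >= free.cost - 1e-12

    def test_infeasible_anchor_pair_raises(self):
        with pytest.raises(InfeasiblePathError):
            shortest_path(
                CostImage(np.zeros((6, 6))), SearchBand.full(6, 6), 1,
                anchors=[AnchorPoint(0, 0), AnchorPoint(2, 5)],
            )

    def test_anchor_outside_band_raises(self):
        band = SearchBand(np.full(5, 2), np.full(5, 4))
        with pytest.raises(ValidationError):
            shortest_path(CostImage(np.zeros((6, 5))), band, 1,
                          anchors=[AnchorPoint(2, 0)])


class TestEstimateRpeRow:
    def _scan(self, img):
        cal = Calibration(3.87, 6.0, img.shape[1])
        return BScan(np.asarray(img, float), cal)

    def test_brightest_row_wins(self):
        img = np.zeros((10, 4))
        img[7] = 1.0
        assert estimate_rpe_row(self._scan(img)) == 7

    def test_tie_goes_to_smaller_row(self):
        img = np.zeros((10, 4))
        img[3] = img[8] = 1.0
        assert estimate_rpe_row(self._scan(img)) == 3

    def test_phantom_rpe_row_inside_band(self, noiseless_phantom):
        res = noiseless_phantom
        norm = normalize_intensity(res.scan)
        row = estimate_rpe_row(norm)
        assert np.all(row > res.truth["ISOS"])
        assert np.all(row <= res.truth["RPE_OUTER"] + 1)


class TestBoundaryTracing:
    def test_degenerate_halfwidth_pins_path(self, noiseless_phantom):
        norm = normalize_intensity(noiseless_phantom.scan)
        initial = estimate_rpe_row(norm)
        bp = segment_rpe_center(norm, initial, band_halfwidth=0)
        np.testing.assert_array_equal(bp.rows, initial)

    def test_noiseless_boundaries_within_one_pixel(self, noiseless_phantom):
        res = noiseless_phantom
        seg = segment_all(res.scan)
        for name, bp in seg.boundaries.items():
            mae = np.abs(bp.rows - res.truth[name]).mean()
            assert mae <= 1.0, f"{name} MAE {mae:.2f}"

    def test_rpe_center_near_band_middle(self, noiseless_phantom):
        res = noiseless_phantom
        seg = segment_all(res.scan)
        dev = np.abs(seg.rpe_center.rows - res.truth["RPE_CENTER"])
        assert dev.max() <= 1.0

    def test_missing_isos_band_flagged_low_confidence(self):
        # erase the IS/OS band: no dark→bright edge left inside the search window
        spec = device_a_spec(
            speckle=False, jitter_max_px=0, level_isos=0.15, level_gap=0.15
        )
        res = generate_phantom(spec, seed=0)
        norm = normalize_intensity(res.scan)
        rc = segment_rpe_center(norm, estimate_rpe_row(norm))
        bp = segment_isos(norm, rc)
        assert bp.low_confidence

    def test_isos_band_present_not_flagged(self, noiseless_phantom):
        norm = normalize_intensity(noiseless_phantom.scan)
        rc = segment_rpe_center(norm, estimate_rpe_row(norm))
        assert not segment_isos(norm, rc).low_confidence

    def test_anchors_are_exact_at_their_columns(self, noiseless_phantom):
        res = noiseless_phantom
        anchor_cols = [100, 256, 400]
        anchors = {
            "ILM": [
                AnchorPoint(c, int(round(res.truth["ILM"][c]))) for c in anchor_cols
            ]
        }
        seg = segment_all(res.scan, anchors=anchors)
        for c in anchor_cols:
            assert seg.ilm.rows[c] == int(round(res.truth["ILM"][c]))

    def test_detached_hyaloid_does_not_capture_ilm(self):
        spec = device_a_spec(
            speckle=False, jitter_max_px=0, hyaloid=True, hyaloid_contrast=0.25
        )
        res = generate_phantom(spec, seed=0)
        seg = segment_all(res.scan)
        mae = np.abs(seg.ilm.rows - res.truth["ILM"]).mean()
        assert mae <= 2.0

    def test_bright_floater_fixed_by_anchors(self):
        # an adversarial hyper-reflective blob in the vitreous
        res = generate_phantom(device_a_spec(speckle=False, jitter_max_px=0), seed=0)
        img = res.scan.image.copy()
        img[8:12, 150:360] = 0.9
        scan = BScan(img, res.scan.calibration, "floater")
        try:
            seg = segment_all(scan)
            captured = np.abs(seg.ilm.rows - res.truth["ILM"]).mean() > 2.0
        except SegmentationOrderingError:
            captured = True
        assert captured, "floater should disturb the unanchored ILM"
        anchors = {
            "ILM": [
                AnchorPoint(c, int(round(res.truth["ILM"][c])))
                for c in (120, 200, 260, 320, 400)
            ]
        }
        seg = segment_all(scan, anchors=anchors)
        assert np.abs(seg.ilm.rows - res.truth["ILM"]).mean() <= 2.0

    def test_band_outside_image_rejected(self, noiseless_phantom):
        norm = normalize_intensity(noiseless_phantom.scan)
        fake_center = type(segment_rpe_center(norm, 0, 0))(
            rows=np.full(norm.n_cols, norm.n_rows - 1), cost=0.0
        )
        with pytest.raises(ValidationError):
            segment_rpe_outer(norm, fake_center, 50.0, 80.0)


class TestSegmentAll:
    def test_deterministic(self, speckled_phantom):
        a = segment_all(speckled_phantom.scan)
        b = segment_all(speckled_phantom.scan)
        for name in a.boundaries:
            np.testing.assert_array_equal(
                a.boundaries[name].rows, b.boundaries[name].rows
            )

    def test_ordering_invariant_on_random_phantoms(self):
        for seed in range(6):
            res = generate_phantom(device_a_spec(), seed=seed)
            seg = segment_all(res.scan)
            assert np.all(seg.ilm.rows <= seg.isos.rows)
            assert np.all(seg.isos.rows <= seg.rpe_center.rows)
            assert np.all(seg.rpe_center.rows <= seg.rpe_outer.rows)

    def test_speckled_boundaries_within_two_pixels(self, speckled_phantom):
        res = speckled_phantom
        seg = segment_all(res.scan)
        for name, bp in seg.boundaries.items():
            mae = np.abs(bp.rows - res.truth[name]).mean()
            assert mae <= 2.0, f"{name} MAE {mae:.2f}"

    def test_json_roundtrip(self, tmp_path, noiseless_phantom):
        seg = segment_all(noiseless_phantom.scan)
        seg.to_json(tmp_path / "seg.json")
        back = LayerSegmentation.from_json(tmp_path / "seg.json")
        for name in seg.boundaries:
            np.testing.assert_array_equal(
                back.boundaries[name].rows, seg.boundaries[name].rows
            )
        assert back.calibration == seg.calibration

    def test_ordering_violation_reports_columns(self):
        import octpath.segmentation as S

        rows = np.zeros(5, dtype=int)
        with pytest.raises(SegmentationOrderingError) as exc:
            LayerSegmentation(
                ilm=S.BoundaryPath(rows + 3, 0.0, "ILM"),
                isos=S.BoundaryPath(rows + 1, 0.0, "ISOS"),
                rpe_center=S.BoundaryPath(rows + 2, 0.0, "RPE_CENTER"),
                rpe_outer=S.BoundaryPath(rows + 4, 0.0, "RPE_OUTER"),
            )
        assert exc.value.columns == (0, 1, 2, 3, 4)


def test_config_file_roundtrip(tmp_path):
    cfg = SegmentationConfig(max_jump=3, ilm_margin_um=40.0)
    (tmp_path / "cfg.yaml").write_text(
        "max_jump: 3\nilm_margin_um: 40.0\n"
    )
    loaded = SegmentationConfig.from_file(tmp_path / "cfg.yaml")
    assert loaded == cfg
    (tmp_path / "bad.yaml").write_text("no_such_key: 1\n")
    with pytest.raises(ValidationError):
        SegmentationConfig.from_file(tmp_path / "bad.yaml")
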