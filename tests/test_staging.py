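"""Triangle-region staging: geometry oracles and classifier recovery."""

import numpy as np
import pytest
from shapely.geometry import Point, Polygon
from sklearn.base import clone

import endospec as es
from endospec.staging import SEVERITY_ORDER, UNDETECTED, evaluate
from endospec.synthetic import make_score_cloud


def _shoelace(a, b, c):
    pts = np.array([a, b, c])
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * abs(
        x[0] * (y[1] - y[2]) + x[1] * (y[2] - y[0]) + x[2] * (y[0] - y[1])
    )


class TestTriangleArea:
    def test_unit_right_triangle(self):
        assert es.triangle_area((0, 0), (1, 0), (0, 1)) == 0.5

    def test_collinear_points_have_zero_area(self):
        assert es.triangle_area((0, 0), (1, 1), (2, 2)) == 0.0

    def test_matches_shoelace_oracle(self, rng):
        for _ in range(200):
            a, b, c = rng.uniform(-5, 5, (3, 2))
            assert es.triangle_area(a, b, c) == pytest.approx(
                _shoelace(a, b, c), abs=1e-12
            )
            # secondary independent check
            assert es.triangle_area(a, b, c) == pytest.approx(
                Polygon([a, b, c]).area, abs=1e-9
            )


class TestPointInTriangle:
    def _region(self):
        return es.TriangleRegion(np.array([[0.0, 0.0], [2.0, 0.0], [0.5, 1.5]]), "t")

    def test_centroid_inside(self):
        region = self._region()
        assert es.point_in_triangle(region.vertices.mean(axis=0), region)

    def test_vertex_on_boundary_counts_inside(self):
        region = self._region()
        assert es.point_in_triangle(region.vertices[0], region)

    def test_matches_barycentric_oracle(self, rng):
        region = self._region()
        a, b, c = region.vertices
        T = np.column_stack([b - a, c - a])
        pts = rng.uniform(-1, 3, (10_000, 2))
        for p in pts:
            alpha, beta = np.linalg.solve(T, p - a)
            margin = min(alpha, beta, 1 - alpha - beta)
            if abs(margin) < 1e-10:  # inside the tolerance band
                continue
            assert es.point_in_triangle(p, region) == (margin > 0)

    def test_degenerate_triangle_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            es.TriangleRegion(np.array([[0, 0], [1, 1], [2, 2]], float), "bad")


def _brute_force_max_triangle(points):
    from itertools import combinations

    best = -1.0
    for i, j, k in combinations(range(len(points)), 3):
        best = max(best, es.triangle_area(points[i], points[j], points[k]))
    return best


class TestMaxAreaTriangle:
    def test_three_points_returned_as_is(self):
        pts = np.array([[0, 0], [3, 0], [1, 2]], float)
        region = es.max_area_triangle(pts, "s")
        assert region.area == pytest.approx(3.0)
        assert {tuple(v) for v in region.vertices} == {tuple(p) for p in pts}

    @pytest.mark.parametrize("n,seed", [(25, 0), (25, 1), (40, 2), (12, 3)])
    def test_hull_search_equals_brute_force(self, n, seed):
        pts = np.random.default_rng(seed).uniform(-2, 2, (n, 2))
        region = es.max_area_triangle(pts)
        assert region.area == pytest.approx(_brute_force_max_triangle(pts), abs=1e-12)

    def test_square_with_interior_points(self, rng):
        corners = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float)
        pts = np.vstack([corners, rng.uniform(0.1, 0.9, (20, 2))])
        region = es.max_area_triangle(pts)
        assert region.area == pytest.approx(0.5)
        assert region.area == pytest.approx(_brute_force_max_triangle(pts), abs=1e-12)

    def test_collinear_points_rejected(self):
        pts = np.column_stack([np.arange(5.0), 2 * np.arange(5.0)])
        with pytest.raises(ValueError, match="collinear"):
            es.max_area_triangle(pts)

    def test_deterministic_tie_break(self):
        # a square's four corners admit four equal-area triangles
        corners = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float)
        a = es.max_area_triangle(corners)
        b = es.max_area_triangle(corners[::-1])
        np.testing.assert_array_equal(a.vertices, b.vertices)


class TestScoreChart:
    def test_rank_one_data_has_zero_spc(self, rng):
        direction = rng.standard_normal(es.DEFAULT_WAVELENGTHS.size)
        spectra = 0.5 + np.outer(rng.uniform(-1, 1, 30), direction) * 0.01
        _, scores = es.fit_score_chart(spectra)
        assert np.abs(scores[:, 1]).max() < 1e-10

    def test_separated_clusters_separate_in_fpc(self, rng):
        wl = es.DEFAULT_WAVELENGTHS
        a = 0.2 + 0.02 * rng.standard_normal((20, wl.size))
        b = 0.7 + 0.02 * rng.standard_normal((20, wl.size))
        _, scores = es.fit_score_chart(np.vstack([a, b]))
        fa, fb = scores[:20, 0], scores[20:, 0]
        assert max(fa.max(), fb.max()) - min(fa.min(), fb.min()) > 0
        assert (fa.max() < fb.min()) or (fb.max() < fa.min())

    def test_score_covariance_diagonal_decreasing(self, checker30):
        _, scores = es.fit_score_chart(checker30)
        cov = np.cov(scores.T)
        assert abs(cov[0, 1]) < 1e-10
        assert cov[0, 0] >= cov[1, 1]

    def test_too_few_spectra_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            es.fit_score_chart(np.zeros((2, 81)))


class TestClassifyPoint:
    def _regions(self):
        return {
            "IPCL_V3_SCC": es.TriangleRegion(
                np.array([[0.0, 0.0], [2.0, 0.0], [1.0, 2.0]]), "IPCL_V3_SCC"
            ),
            "IPCL_V1_SCC": es.TriangleRegion(
                np.array([[1.0, 0.0], [3.0, 0.0], [2.0, 2.0]]), "IPCL_V1_SCC"
            ),
        }

    def test_point_in_single_region(self):
        pred = es.classify_point((0.5, 0.3), self._regions())
        assert pred.stage == "IPCL_V3_SCC" and not pred.undetected

    def test_point_outside_all_regions_undetected(self):
        pred = es.classify_point((-5.0, -5.0), self._regions())
        assert pred.undetected and pred.stage == UNDETECTED

    def test_overlap_resolved_by_severity_order(self):
        # (1.5, 0.5) lies in both triangles; V3 SCC is tested first
        pred = es.classify_point((1.5, 0.5), self._regions())
        assert pred.stage == "IPCL_V3_SCC"
        assert SEVERITY_ORDER.index("IPCL_V3_SCC") < SEVERITY_ORDER.index("IPCL_V1_SCC")

    def test_empty_region_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            es.classify_point((0, 0), {})


class TestPatientScore:
    def test_single_spectrum_is_own_score(self, checker30):
        basis, scores = es.fit_score_chart(checker30)
        np.testing.assert_allclose(
            es.patient_score(checker30[3], basis), scores[3, :2], atol=1e-10
        )

    def test_mean_of_scores_equals_score_of_mean(self, checker30):
        basis, scores = es.fit_score_chart(checker30)
        np.testing.assert_allclose(
            es.patient_score(checker30, basis), scores[:, :2].mean(axis=0), atol=1e-10
        )

    def test_roi_sized_input_yields_one_score(self, checker30, rng):
        basis, _ = es.fit_score_chart(checker30)
        pixels = checker30[rng.integers(0, 30, 2500)]
        score = es.patient_score(pixels, basis)
        assert score.shape == (2,)

    def test_empty_input_rejected(self, checker30):
        basis, _ = es.fit_score_chart(checker30)
        with pytest.raises(ValueError):
            es.patient_score(np.empty((0, 81)), basis)


class TestEvaluate:
    def test_perfect_predictions(self):
        truth = ["IPCL_IV", "IPCL_V3_SCC", "IPCL_IV", "IPCL_V1_SCC"]
        metrics = evaluate(truth, truth)
        for m in metrics.values():
            assert m["sensitivity"] == 1.0 and m["specificity"] == 1.0

    def test_all_undetected(self):
        truth = ["IPCL_IV"] * 3 + ["IPCL_V3_SCC"] * 3
        metrics = evaluate([UNDETECTED] * 6, truth)
        for m in metrics.values():
            assert m["sensitivity"] == 0.0 and m["specificity"] == 1.0

    def test_hand_built_confusion_table(self):
        # 20 cases, tallied by hand:
        # stage A: 6 true, 4 predicted A (TP=4, FN=2); 2 false A calls (FP=2)
        truth = ["A"] * 6 + ["B"] * 14
        pred = ["A"] * 4 + ["B"] * 2 + ["A"] * 2 + ["B"] * 10 + [UNDETECTED] * 2
        m = evaluate(pred, truth)
        assert m["A"]["sensitivity"] == pytest.approx(4 / 6)
        assert m["A"]["specificity"] == pytest.approx(12 / 14)
        assert m["B"]["sensitivity"] == pytest.approx(10 / 14)
        assert m["B"]["specificity"] == pytest.approx(4 / 6)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            evaluate(["A"], ["A", "B"])


class TestTriangleStageClassifier:
    def test_disjoint_clouds_recovered_perfectly(self):
        scores, labels = make_score_cloud(n_per_class=200, seed=3)
        clf = es.TriangleStageClassifier().fit(scores, labels)
        metrics = evaluate(clf.predict(scores), labels)
        for m in metrics.values():
            assert m["sensitivity"] == 1.0 and m["specificity"] == 1.0

    def test_overlap_degrades_lower_priority_sensitivity(self):
        hi = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        lo = np.array([[0.5, -0.5], [1.5, -0.5], [0.5, 0.5]])
        f = Polygon(hi).intersection(Polygon(lo)).area / Polygon(lo).area
        scores, labels = make_score_cloud(
            {"IPCL_V3_SCC": hi, "IPCL_V1_SCC": lo}, n_per_class=500, seed=5
        )
        clf = es.TriangleStageClassifier().fit(scores, labels)
        metrics = evaluate(clf.predict(scores), labels)
        sens = metrics["IPCL_V1_SCC"]["sensitivity"]
        # binomial tolerance: 4 sigma at n = 500
        tol = 4 * np.sqrt(f * (1 - f) / 500)
        assert abs(sens - (1 - f)) < tol
        assert metrics["IPCL_V3_SCC"]["sensitivity"] == 1.0

    def test_fitted_regions_membership_consistent_with_shapely(self):
        scores, labels = make_score_cloud(n_per_class=100, seed=1)
        clf = es.TriangleStageClassifier().fit(scores, labels)
        rng = np.random.default_rng(0)
        pts = rng.uniform(-4, 3, (500, 2))
        for stage, region in clf.regions_.items():
            poly = Polygon(region.vertices)
            for p in pts:
                if abs(poly.exterior.distance(Point(p))) < 1e-9:
                    continue
                assert es.point_in_triangle(p, region) == poly.covers(Point(p))

    def test_manual_vertices_override(self):
        scores, labels = make_score_cloud(n_per_class=50, seed=2)
        tri = np.array([[-10.0, -10.0], [-9.0, -10.0], [-9.5, -9.0]])
        clf = es.TriangleStageClassifier(
            manual_vertices={"IPCL_IV": tri}
        ).fit(scores, labels)
        np.testing.assert_array_equal(clf.regions_["IPCL_IV"].vertices, tri)

    def test_sklearn_clone_compatible(self):
        clf = es.TriangleStageClassifier(rel_tol=1e-8)
        assert clone(clf).get_params()["rel_tol"] == 1e-8

    def test_classifies_from_raw_spectra_via_score_chart(self, rng):
        wl = es.DEFAULT_WAVELENGTHS
        a = 0.2 + 0.01 * rng.standard_normal((30, wl.size))
        b = 0.7 + 0.01 * rng.standard_normal((30, wl.size))
        X = np.vstack([a, b])
        y = np.array(["IPCL_V3_SCC"] * 30 + ["IPCL_IV"] * 30)
        clf = es.TriangleStageClassifier().fit(X, y)
        assert clf.score_basis_ is not None
        pred = clf.predict(X)
        # well-separated classes: never cross-classified, only the points
        # outside their class's peripheral triangle go undetected
        assert set(pred[:30]) <= {"IPCL_V3_SCC", UNDETECTED}
        assert set(pred[30:]) <= {"IPCL_IV", UNDETECTED}
        assert (pred == np.asarray(y)).mean() > 0.3
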