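"""Triangle-region staging of esophageal neoplasia in PC-score space.

Estimated reflectance spectra are reduced by mean-centered PCA to a
first/second principal-component (FPC, SPC) score chart.  For each IPCL
stage, the maximum-area triangle over the stage's training scores is
taken as its decision region.  A test point ``U`` belongs to triangle
``ABC`` when the three sub-triangle areas tile the whole:

    area(UAB) + area(UBC) + area(UAC) == area(ABC)

with ``area`` the half cross-product magnitude.  Floating-point
equality is replaced by a relative tolerance (default ``1e-9`` of the
triangle area), and the boundary counts as inside.  Regions are tested
in severity-descending order — IPCL-V3 SCC, IPCL-V1 SCC, IPCL-V1 HGD,
IPCL-IV — and the first membership wins; a point in no region is
reported as undetected.

The maximum-area triangle search is restricted to convex-hull vertices
(the maximizer's vertices are always hull points) with exhaustive
enumeration over the hull and lexicographic tie-breaking, which is both
deterministic and exact.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .reconstruction import SpectralBasisPCA

__all__ = [
    "SEVERITY_ORDER",
    "UNDETECTED",
    "TriangleRegion",
    "StagePrediction",
    "fit_score_chart",
    "triangle_area",
    "point_in_triangle",
    "max_area_triangle",
    "classify_point",
    "patient_score",
    "evaluate",
    "TriangleStageClassifier",
]

#: Region test order, most severe first.
SEVERITY_ORDER = ("IPCL_V3_SCC", "IPCL_V1_SCC", "IPCL_V1_HGD", "IPCL_IV")

#: Label used when a point lies in no stage triangle.
UNDETECTED = "undetected"


@dataclass(frozen=True)
class TriangleRegion:
    """A stage's decision triangle in (FPC, SPC) space."""

    vertices: np.ndarray  # (3, 2)
    stage: str

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        if v.shape != (3, 2):
            raise ValueError("a triangle needs exactly three 2-D vertices")
        object.__setattr__(self, "vertices", v)
        if triangle_area(*v) <= 0:
            raise ValueError(f"degenerate triangle for stage {self.stage!r}")

    @property
    def area(self) -> float:
        return triangle_area(*self.vertices)


@dataclass(frozen=True)
class StagePrediction:
    """Assigned stage (or undetected) with per-region area diagnostics."""

    stage: str  # a stage label, or UNDETECTED
    area_sums: dict  # stage -> (sum of sub-triangle areas, region area)

    @property
    def undetected(self) -> bool:
        return self.stage == UNDETECTED


def triangle_area(a, b, c) -> float:
    """Area of triangle ABC: half the cross-product magnitude.

    ``area = 0.5 * |det[B - A, C - A]|``; collinear points give 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    return 0.5 * abs(
        (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
    )


def point_in_triangle(x, region: TriangleRegion, rel_tol: float = 1e-9) -> bool:
    """Area-sum membership test, boundary inclusive.

    ``x`` is inside (or on the edge of) the triangle iff the areas of
    the three sub-triangles it forms with the edges sum to the triangle
    area; strictly outside, the sum strictly exceeds it.  The equality
    is tested as ``sum <= area * (1 + rel_tol)``.
    """
    area = region.area
    if area <= 0:
        raise ValueError("degenerate triangle")
    a, b, c = region.vertices
    s = triangle_area(x, a, b) + triangle_area(x, b, c) + triangle_area(x, a, c)
    return s <= area * (1.0 + rel_tol)


def max_area_triangle(points, stage: str = "") -> TriangleRegion:
    """Largest triangle with vertices among ``points``.

    The maximizer's vertices always lie on the convex hull, so the
    exhaustive search runs over hull vertices only (exact, and cheap for
    the point counts of score charts).  Ties are broken by the
    lexicographically smallest sorted vertex tuple, making the result
    deterministic.

    Raises
    ------
    ValueError
        For fewer than 3 points or an all-collinear point set.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (n, 2)")
    if len(pts) < 3:
        raise ValueError("need at least 3 points")
    try:
        hull = ConvexHull(pts)
        candidates = pts[hull.vertices]
    except QhullError as exc:
        raise ValueError("all points are collinear: no triangle exists") from exc
    best_area = -1.0
    best_key = None
    best = None
    for tri in combinations(range(len(candidates)), 3):
        v = candidates[list(tri)]
        area = triangle_area(*v)
        key = tuple(sorted(map(tuple, v)))
        if area > best_area + 1e-15 or (
            abs(area - best_area) <= 1e-15 and (best_key is None or key < best_key)
        ):
            best_area, best_key, best = area, key, v
    if best_area <= 0:
        raise ValueError("all points are collinear: no triangle exists")
    return TriangleRegion(np.array(best_key, dtype=float), stage)


def fit_score_chart(spectra, n_components: int = 2):
    """PCA score chart of a spectrum collection.

    Returns ``(basis, scores)`` where ``scores[:, 0]`` is the FPC and
    ``scores[:, 1]`` the SPC of each spectrum (mean-centered PCA with
    the package's deterministic sign convention).
    """
    spectra = np.asarray(spectra, dtype=float)
    if spectra.shape[0] < 3:
        raise ValueError("need at least 3 spectra for a score chart")
    basis = SpectralBasisPCA(n_components=n_components).fit(spectra)
    return basis, basis.transform(spectra)


def classify_point(
    x, regions, order=SEVERITY_ORDER, rel_tol: float = 1e-9
) -> StagePrediction:
    """Assign a stage to one score point by ordered triangle membership.

    ``regions`` maps stage label to :class:`TriangleRegion`.  Regions
    are tested in ``order`` (severity-descending by default); the first
    membership wins, and a point in no triangle is undetected.
    """
    if not regions:
        raise ValueError("empty region set")
    diagnostics = {}
    hit = UNDETECTED
    for stage in order:
        if stage not in regions:
            continue
        region = regions[stage]
        a, b, c = region.vertices
        s = (
            triangle_area(x, a, b)
            + triangle_area(x, b, c)
            + triangle_area(x, a, c)
        )
        diagnostics[stage] = (s, region.area)
        if hit == UNDETECTED and s <= region.area * (1.0 + rel_tol):
            hit = stage
    return StagePrediction(hit, diagnostics)


def patient_score(pixel_spectra, basis: SpectralBasisPCA) -> np.ndarray:
    """Patient-level (FPC, SPC): mean score of the sampled pixel spectra.

    Because the projection is linear, the mean of per-pixel scores
    equals the score of the mean spectrum; both are computed and checked
    against each other as an internal consistency assertion.
    """
    spectra = np.atleast_2d(np.asarray(pixel_spectra, dtype=float))
    if spectra.shape[0] < 1 or spectra.size == 0:
        raise ValueError("need at least one spectrum")
    mean_of_scores = basis.transform(spectra).mean(axis=0)[:2]
    score_of_mean = basis.transform(spectra.mean(axis=0)[None, :])[0, :2]
    if not np.allclose(mean_of_scores, score_of_mean, atol=1e-10):
        raise AssertionError("linearity violated: mean score != score of mean")
    return mean_of_scores


def evaluate(predictions, truth):
    """One-vs-rest sensitivity and specificity per stage.

    ``predictions`` holds :class:`StagePrediction` objects or plain
    labels; undetected predictions count as negative for every stage.
    Returns a dict ``stage -> {"sensitivity", "specificity", "tp",
    "fn", "tn", "fp"}``; a sensitivity or specificity with an empty
    denominator is reported as ``nan``.
    """
    pred_labels = [
        p.stage if isinstance(p, StagePrediction) else str(p) for p in predictions
    ]
    truth = [str(t) for t in truth]
    if len(pred_labels) != len(truth):
        raise ValueError("predictions and truth differ in length")
    stages = sorted(set(truth))
    out = {}
    for stage in stages:
        tp = sum(1 for p, t in zip(pred_labels, truth) if t == stage and p == stage)
        fn = sum(1 for p, t in zip(pred_labels, truth) if t == stage and p != stage)
        fp = sum(1 for p, t in zip(pred_labels, truth) if t != stage and p == stage)
        tn = sum(1 for p, t in zip(pred_labels, truth) if t != stage and p != stage)
        out[stage] = {
            "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
            "specificity": tn / (tn + fp) if tn + fp else float("nan"),
            "tp": tp,
            "fn": fn,
            "fp": fp,
            "tn": tn,
        }
    return out


class TriangleStageClassifier(BaseEstimator, ClassifierMixin):
    """Stage assignment by per-class maximum-area triangles in score space.

    ``fit`` accepts either raw spectra (any number of columns; a 2-D
    PCA score chart is fitted first) or ready (FPC, SPC) pairs (exactly
    2 columns, used as-is), plus the per-sample stage labels.  For each
    class the maximum-area triangle over its training scores defines
    the decision region; ``predict`` tests regions in severity order
    and returns the first hit, or ``"undetected"``.

    Parameters
    ----------
    rel_tol : float
        Relative tolerance of the area-sum membership equality.
    test_order : sequence of str or None
        Region test order; defaults to severity-descending for the
        known IPCL stages, with any other labels appended sorted.
    manual_vertices : dict or None
        Optional ``stage -> (3, 2) array`` overriding the automatic
        max-area search for those stages (the hand-picked "peripheral
        points" alternative).

    Attributes
    ----------
    regions_ : dict stage -> TriangleRegion
    score_basis_ : SpectralBasisPCA or None (None when fed scores)
    classes_ : ndarray of fitted stage labels
    """

    def __init__(self, rel_tol: float = 1e-9, test_order=None, manual_vertices=None):
        self.rel_tol = rel_tol
        self.test_order = test_order
        self.manual_vertices = manual_vertices

    def _order(self, labels):
        if self.test_order is not None:
            return tuple(self.test_order)
        known = [s for s in SEVERITY_ORDER if s in labels]
        extra = sorted(set(labels) - set(SEVERITY_ORDER))
        return tuple(known + extra)

    def _scores(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        if X.shape[1] == 2 and self.score_basis_ is None:
            return X
        if self.score_basis_ is None:
            raise ValueError(
                f"classifier was fitted on 2-D scores but got {X.shape[1]} columns"
            )
        return self.score_basis_.transform(X)

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y differ in length")
        if X.shape[1] == 2:
            self.score_basis_ = None
            scores = X
        else:
            self.score_basis_, scores = fit_score_chart(X)
        self.classes_ = np.unique(y)
        manual = self.manual_vertices or {}
        self.regions_ = {}
        for stage in self.classes_:
            if stage in manual:
                self.regions_[stage] = TriangleRegion(
                    np.asarray(manual[stage], dtype=float), str(stage)
                )
            else:
                self.regions_[stage] = max_area_triangle(
                    scores[y == stage], stage=str(stage)
                )
        self.test_order_ = self._order(set(map(str, self.classes_)))
        return self

    def predict_one(self, x) -> StagePrediction:
        check_is_fitted(self, "regions_")
        return classify_point(
            x, self.regions_, order=self.test_order_, rel_tol=self.rel_tol
        )

    def predict(self, X):
        check_is_fitted(self, "regions_")
        scores = self._scores(X)
        return np.array(
            [
                classify_point(
                    s, self.regions_, order=self.test_order_, rel_tol=self.rel_tol
                ).stage
                for s in scores
            ]
        )
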