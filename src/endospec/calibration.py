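"""Colorimetric calibration between an endoscope camera and a spectrophotometer.

Commercial endoscopes emit 8-bit sRGB frames whose reference white (the
xenon lamp) differs from the light used to measure a color checker with
a spectrophotometer.  Calibration therefore chains:

1. sRGB decoding to linear RGB,
2. a Bradford chromatic-adaptation transform between the two whites,
3. a per-channel third-order polynomial regression from the 20-term
   monomial expansion of linear RGB to the target values (XYZ triples
   or spectral-basis coefficients; both pathways share the expansion).

The regression is exposed as the scikit-learn style estimator
:class:`PolynomialColorCorrection`; :func:`fit_color_transform` is a thin
functional wrapper.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .spectra import cie_1931_cmfs

__all__ = [
    "srgb_decode",
    "srgb_encode",
    "xyz_from_spectrum",
    "chromatic_adaptation_matrix",
    "chromatic_adapt",
    "poly_expand3",
    "FEATURE_ORDER",
    "PolynomialColorCorrection",
    "fit_color_transform",
    "SRGB_RGB_TO_XYZ",
    "SRGB_XYZ_TO_RGB",
]

#: Fixed monomial ordering of the degree-<=3 feature expansion.  Frozen:
#: serialized models reference this ordering explicitly.
FEATURE_ORDER = (
    "1",
    "R", "G", "B",
    "R2", "G2", "B2", "RG", "RB", "GB",
    "R3", "G3", "B3", "R2G", "R2B", "G2R", "G2B", "B2R", "B2G", "RGB",
)

# Bradford sharpened cone-response matrix (Lam 1985), the field-standard
# chromatic adaptation for camera characterization.
_BRADFORD = np.array(
    [
        [0.8951, 0.2664, -0.1614],
        [-0.7502, 1.7135, 0.0367],
        [0.0389, -0.0685, 1.0296],
    ]
)
_BRADFORD_INV = np.linalg.inv(_BRADFORD)

# sRGB (IEC 61966-2-1) linear-RGB <-> XYZ (D65) matrices, Y of white = 1.
SRGB_RGB_TO_XYZ = np.array(
    [
        [0.4124564, 0.3575761, 0.1804375],
        [0.2126729, 0.7151522, 0.0721750],
        [0.0193339, 0.1191920, 0.9503041],
    ]
)
SRGB_XYZ_TO_RGB = np.linalg.inv(SRGB_RGB_TO_XYZ)


def srgb_decode(image: np.ndarray) -> np.ndarray:
    """Decode 8-bit sRGB values to linear RGB in [0, 1].

    Applies the standard piecewise sRGB electro-optical transfer
    function per channel.  Accepts any array shape; values (integer or
    float) are interpreted on the 0-255 scale.
    """
    v = np.asarray(image).astype(float) / 255.0
    return np.where(v <= 0.04045, v / 12.92, ((v + 0.055) / 1.055) ** 2.4)


def srgb_encode(linear: np.ndarray) -> np.ndarray:
    """Inverse of :func:`srgb_decode`: linear RGB in [0,1] to encoded [0,1]."""
    v = np.clip(np.asarray(linear, dtype=float), 0.0, 1.0)
    return np.where(v <= 0.0031308, v * 12.92, 1.055 * v ** (1.0 / 2.4) - 0.055)


def xyz_from_spectrum(
    spectrum: np.ndarray,
    illuminant_spd: np.ndarray,
    cmfs: np.ndarray | None = None,
    wavelengths: np.ndarray | None = None,
) -> np.ndarray:
    """CIE XYZ tristimulus values of reflectance spectra under an illuminant.

    X, Y, Z = k * sum(reflectance * illuminant * cmf) with k chosen so a
    unit reflector has Y = 100.  ``spectrum`` may be a single spectrum
    or an (n, n_wavelengths) stack.

    Raises
    ------
    ValueError
        If curve lengths disagree (wavelength-grid mismatch).
    """
    spec = np.atleast_2d(np.asarray(spectrum, dtype=float))
    ill = np.asarray(illuminant_spd, dtype=float)
    if cmfs is None:
        cmfs = cie_1931_cmfs(wavelengths)
    if not (spec.shape[1] == ill.shape[0] == cmfs.shape[0]):
        raise ValueError(
            "wavelength grid mismatch between spectrum "
            f"({spec.shape[1]}), illuminant ({ill.shape[0]}) and CMFs ({cmfs.shape[0]})"
        )
    k = 100.0 / float(ill @ cmfs[:, 1])
    xyz = k * (spec * ill) @ cmfs
    return xyz[0] if np.asarray(spectrum).ndim == 1 else xyz


def chromatic_adaptation_matrix(src_white: np.ndarray, dst_white: np.ndarray) -> np.ndarray:
    """3x3 Bradford (von Kries-style) adaptation matrix in XYZ space.

    Maps ``src_white`` exactly to ``dst_white`` by scaling sharpened
    cone responses.  Both whites are XYZ triples with positive Y.
    """
    src = np.asarray(src_white, dtype=float)
    dst = np.asarray(dst_white, dtype=float)
    if src.shape != (3,) or dst.shape != (3,):
        raise ValueError("white points must be XYZ triples")
    if src[1] <= 0 or dst[1] <= 0:
        raise ValueError("white points must have positive Y")
    cone_src = _BRADFORD @ src
    cone_dst = _BRADFORD @ dst
    if np.any(cone_src == 0):
        raise ValueError("degenerate source white: zero cone response")
    return _BRADFORD_INV @ np.diag(cone_dst / cone_src) @ _BRADFORD


def chromatic_adapt(
    xyz: np.ndarray, src_white: np.ndarray, dst_white: np.ndarray
) -> np.ndarray:
    """Adapt XYZ values from a source white to a destination white."""
    m = chromatic_adaptation_matrix(src_white, dst_white)
    return np.asarray(xyz, dtype=float) @ m.T


def poly_expand3(rgb: np.ndarray) -> np.ndarray:
    """Expand linear RGB into all 20 monomials of total degree <= 3.

    The output ordering is :data:`FEATURE_ORDER`:
    1; R, G, B; R2, G2, B2, RG, RB, GB; R3, G3, B3, R2G, R2B, G2R, G2B,
    B2R, B2G, RGB.  Accepts a single triple or an (..., 3) array; the
    feature axis is appended last.
    """
    arr = np.asarray(rgb, dtype=float)
    if arr.shape[-1] != 3:
        raise ValueError("last axis must hold (R, G, B)")
    r, g, b = arr[..., 0], arr[..., 1], arr[..., 2]
    feats = np.stack(
        [
            np.ones_like(r),
            r, g, b,
            r * r, g * g, b * b, r * g, r * b, g * b,
            r ** 3, g ** 3, b ** 3,
            r * r * g, r * r * b, g * g * r, g * g * b, b * b * r, b * b * g,
            r * g * b,
        ],
        axis=-1,
    )
    return feats


class PolynomialColorCorrection(BaseEstimator, RegressorMixin):
    """Per-channel third-order polynomial map from linear camera RGB to targets.

    Optionally applies a Bradford chromatic adaptation to the camera
    values before the polynomial (the camera's scene white differs from
    the spectrophotometer's measurement white).  The adaptation acts in
    XYZ space via the sRGB primary matrices, since the camera output is
    sRGB-encoded colorimetric estimates.

    Parameters
    ----------
    src_white, dst_white : XYZ triples or None
        Whites of the camera scene and of the target measurements.
        Both None disables adaptation.

    Attributes
    ----------
    coef_ : ndarray, shape (n_targets, 20)
        One regression vector per output channel, ordered by
        :data:`FEATURE_ORDER`.
    adaptation_matrix_ : ndarray, shape (3, 3)
        The fitted Bradford matrix (identity when adaptation disabled).
    residual_rmse_ : float
        Root-mean-square training residual over all targets.
    """

    #: minimum patches: the expansion has 20 features per channel
    MIN_PATCHES = 20

    def __init__(self, src_white=None, dst_white=None):
        self.src_white = src_white
        self.dst_white = dst_white

    def _adapt(self, rgb_linear: np.ndarray) -> np.ndarray:
        if self.src_white is None and self.dst_white is None:
            return rgb_linear
        if self.src_white is None or self.dst_white is None:
            raise ValueError("src_white and dst_white must be given together")
        xyz = rgb_linear @ SRGB_RGB_TO_XYZ.T
        adapted = chromatic_adapt(xyz, self.src_white, self.dst_white)
        return adapted @ SRGB_XYZ_TO_RGB.T

    def fit(self, X, y):
        """Fit the polynomial from linear RGB rows ``X`` to target rows ``y``."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if y.ndim == 1:
            y = y[:, None]
        if X.ndim != 2 or X.shape[1] != 3:
            raise ValueError("X must be (n_patches, 3) linear RGB")
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y must have the same number of patches")
        if X.shape[0] < self.MIN_PATCHES:
            raise ValueError(
                f"need >= {self.MIN_PATCHES} patches for a rank-{self.MIN_PATCHES} "
                f"degree-3 expansion, got {X.shape[0]}"
            )
        design = poly_expand3(self._adapt(X))
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise ValueError(
                "rank-deficient design matrix: patches do not span the "
                "degree-3 feature space (duplicate or degenerate patches?)"
            )
        coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
        self.coef_ = coef.T
        if self.src_white is None:
            self.adaptation_matrix_ = np.eye(3)
        else:
            self.adaptation_matrix_ = chromatic_adaptation_matrix(
                np.asarray(self.src_white, float), np.asarray(self.dst_white, float)
            )
        resid = design @ coef - y
        self.residual_rmse_ = float(np.sqrt(np.mean(resid ** 2)))
        self.n_features_in_ = 3
        return self

    def predict(self, X):
        """Map linear RGB rows to the fitted target space."""
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=float)
        single = X.ndim == 1
        feats = poly_expand3(self._adapt(np.atleast_2d(X)))
        out = feats @ self.coef_.T
        return out[0] if single else out


def fit_color_transform(camera_rgbs, targets, src_white=None, dst_white=None):
    """Fit a :class:`PolynomialColorCorrection` (functional convenience)."""
    return PolynomialColorCorrection(src_white=src_white, dst_white=dst_white).fit(
        camera_rgbs, targets
    )
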