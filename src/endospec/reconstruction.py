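"""Per-pixel reflectance estimation from RGB endoscopic frames (HSEI core).

The estimation chain has three fitted parts:

1. **Spectral basis** — mean-centered PCA of a spectral library reduces
   each reflectance spectrum to ``k`` coefficients (smooth visible
   reflectances are classically low-dimensional; the default ``k=6``).
2. **Transformation matrix** — a least-squares map from the 20-term
   third-order polynomial expansion of linear camera RGB to the basis
   coefficients of the calibration patches.
3. **Per-pixel estimation** — decode sRGB, chromatically adapt, expand,
   apply the matrix and re-synthesize ``mean + sum(c_i * component_i)``.

Outputs are clipped to [0, 1.2] rather than [0, 1]: estimates above 1
signal calibration failure and are counted rather than silently
saturated.

:class:`SpectralReconstructor` bundles the chain as a scikit-learn style
estimator; the module-level functions expose the individual steps.
"""

from __future__ import annotations

import logging

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_is_fitted

from .calibration import (
    SRGB_RGB_TO_XYZ,
    SRGB_XYZ_TO_RGB,
    chromatic_adapt,
    poly_expand3,
    srgb_decode,
)
from .spectra import DEFAULT_WAVELENGTHS

logger = logging.getLogger(__name__)

__all__ = [
    "SpectralBasisPCA",
    "fit_spectral_basis",
    "fit_transformation_matrix",
    "SpectralReconstructor",
    "estimate_pixel_spectrum",
    "roi_average_spectrum",
]


class SpectralBasisPCA(BaseEstimator, TransformerMixin):
    """Mean-centered PCA basis for reflectance spectra.

    A thin wrapper over :class:`sklearn.decomposition.PCA` (full SVD)
    that adds a deterministic sign convention — each component is
    flipped so its largest-magnitude element is positive — making
    serialized bases reproducible across library orderings and runs.

    Attributes
    ----------
    mean_ : ndarray (n_wavelengths,)
    components_ : ndarray (k, n_wavelengths), orthonormal rows
    explained_variance_ : ndarray (k,), decreasing
    """

    def __init__(self, n_components: int = 6):
        self.n_components = n_components

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("library must be (n_spectra, n_wavelengths)")
        if not 1 <= self.n_components < X.shape[0]:
            raise ValueError(
                f"need library size > n_components >= 1; got {X.shape[0]} spectra "
                f"for k={self.n_components}"
            )
        pca = PCA(n_components=self.n_components, svd_solver="full").fit(X)
        comps = pca.components_.copy()
        for i, comp in enumerate(comps):
            if comp[np.argmax(np.abs(comp))] < 0:
                comps[i] = -comp
        self.mean_ = pca.mean_
        self.components_ = comps
        self.explained_variance_ = pca.explained_variance_
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        """Project spectra onto the basis: coefficients (n, k)."""
        check_is_fitted(self, "components_")
        X = np.asarray(X, dtype=float)
        return (X - self.mean_) @ self.components_.T

    def inverse_transform(self, coeffs):
        """Re-synthesize spectra from coefficients: mean + coeffs @ components."""
        check_is_fitted(self, "components_")
        return np.asarray(coeffs, dtype=float) @ self.components_ + self.mean_


def fit_spectral_basis(library, k: int = 6) -> SpectralBasisPCA:
    """Fit a ``k``-component PCA basis to a spectral library."""
    return SpectralBasisPCA(n_components=k).fit(library)


def fit_transformation_matrix(features, coefficients):
    """Least-squares map from 20-dim RGB features to basis coefficients.

    Parameters
    ----------
    features : (n_patches, 20)
        Polynomial expansions of the calibration-patch camera values.
    coefficients : (n_patches, k)
        Basis projections of the measured patch spectra.

    Returns
    -------
    matrix : ndarray (k, 20)
    residual_rmse : ndarray (k,)
        Per-component root-mean-square training residual.
    """
    F = np.asarray(features, dtype=float)
    C = np.asarray(coefficients, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    if F.ndim != 2 or F.shape[1] != 20:
        raise ValueError("features must be (n_patches, 20)")
    if F.shape[0] != C.shape[0]:
        raise ValueError("features and coefficients disagree in patch count")
    if F.shape[0] < 20:
        raise ValueError(f"need >= 20 patches, got {F.shape[0]}")
    if np.linalg.matrix_rank(F) < F.shape[1]:
        raise ValueError("rank-deficient feature matrix: degenerate patch set")
    sol, _, _, _ = np.linalg.lstsq(F, C, rcond=None)
    resid = F @ sol - C
    return sol.T, np.sqrt(np.mean(resid ** 2, axis=0))


class SpectralReconstructor(BaseEstimator):
    """Fitted RGB-to-reflectance estimator for endoscopic frames.

    ``fit`` takes the calibration-patch spectra (the spectrophotometer
    measurements) and the corresponding camera RGB values; ``predict``
    maps an 8-bit RGB image (or single pixels) to reflectance spectra.

    Parameters
    ----------
    n_components : int
        Spectral basis dimension ``k`` (default 6).
    src_white, dst_white : XYZ triples or None
        Camera-scene and measurement white points for Bradford
        adaptation; both None disables adaptation.
    clip_band : (low, high)
        Output clipping band.  The default (0, 1.2) deliberately allows
        super-unity estimates so calibration failures surface in the
        ``last_clip_count_`` diagnostic instead of being hidden.

    Attributes
    ----------
    basis_ : SpectralBasisPCA
    transformation_matrix_ : ndarray (k, 20)
    residual_rmse_ : ndarray (k,), training residual per component
    last_clip_count_ : int, pixels clipped in the most recent predict
    """

    def __init__(
        self,
        n_components: int = 6,
        src_white=None,
        dst_white=None,
        clip_band: tuple[float, float] = (0.0, 1.2),
        wavelengths=None,
    ):
        self.n_components = n_components
        self.src_white = src_white
        self.dst_white = dst_white
        self.clip_band = clip_band
        self.wavelengths = wavelengths

    # -- internal: shared camera-side front end (decode + adapt + expand)
    def _features(self, rgb) -> np.ndarray:
        arr = np.asarray(rgb)
        if arr.shape[-1] != 3:
            raise ValueError("RGB input must have 3 channels on the last axis")
        linear = srgb_decode(arr)
        if self.src_white is not None and self.dst_white is not None:
            xyz = linear @ SRGB_RGB_TO_XYZ.T
            xyz = chromatic_adapt(xyz, self.src_white, self.dst_white)
            linear = xyz @ SRGB_XYZ_TO_RGB.T
        elif (self.src_white is None) != (self.dst_white is None):
            raise ValueError("src_white and dst_white must be given together")
        return poly_expand3(linear)

    def fit(self, patch_spectra, patch_rgbs):
        """Fit basis and transformation matrix from calibration patches."""
        spectra = np.asarray(patch_spectra, dtype=float)
        self.basis_ = SpectralBasisPCA(n_components=self.n_components).fit(spectra)
        feats = self._features(patch_rgbs)
        coeffs = self.basis_.transform(spectra)
        self.transformation_matrix_, self.residual_rmse_ = fit_transformation_matrix(
            feats, coeffs
        )
        self.wavelengths_ = (
            DEFAULT_WAVELENGTHS.copy()
            if self.wavelengths is None
            else np.asarray(self.wavelengths, dtype=float)
        )
        if self.wavelengths_.size != spectra.shape[1]:
            raise ValueError(
                f"wavelength grid ({self.wavelengths_.size}) does not match "
                f"library spectra ({spectra.shape[1]})"
            )
        self.last_clip_count_ = 0
        return self

    def predict(self, rgb):
        """Estimate reflectance spectra for 8-bit RGB pixels or images.

        Accepts shape ``(3,)``, ``(n, 3)`` or ``(H, W, 3)``; the output
        appends the wavelength axis.  Vectorized over pixels; identical
        to per-pixel looping by construction.
        """
        check_is_fitted(self, "transformation_matrix_")
        feats = self._features(rgb)
        coeffs = feats @ self.transformation_matrix_.T
        if coeffs.shape[-1] != self.basis_.components_.shape[0]:
            raise ValueError("dimension mismatch between matrix and basis")
        spectra = self.basis_.inverse_transform(coeffs)
        lo, hi = self.clip_band
        n_clip = int(np.count_nonzero((spectra < lo) | (spectra > hi)))
        self.last_clip_count_ = n_clip
        if n_clip:
            logger.info("clipped %d reflectance samples to [%g, %g]", n_clip, lo, hi)
        return np.clip(spectra, lo, hi)


def estimate_pixel_spectrum(rgb_8bit, reconstructor: SpectralReconstructor):
    """Reflectance spectrum of one 8-bit RGB pixel under a fitted model."""
    return reconstructor.predict(np.asarray(rgb_8bit))


def roi_average_spectrum(image, roi, reconstructor: SpectralReconstructor):
    """Mean estimated spectrum over a rectangular region of interest.

    Parameters
    ----------
    image : (H, W, 3) 8-bit RGB
    roi : (row, col, height, width)
        Top-left corner plus extent; must lie inside the image.

    Returns
    -------
    spectrum : ndarray (n_wavelengths,)
    n_pixels : int
        Number of per-pixel spectra averaged (height * width).
    """
    image = np.asarray(image)
    r, c, h, w = (int(v) for v in roi)
    if h <= 0 or w <= 0:
        raise ValueError("ROI extent must be positive")
    if r < 0 or c < 0 or r + h > image.shape[0] or c + w > image.shape[1]:
        raise ValueError(f"ROI {roi} falls outside image of shape {image.shape[:2]}")
    patch = image[r : r + h, c : c + w]
    spectra = reconstructor.predict(patch)
    return spectra.reshape(h * w, -1).mean(axis=0), h * w
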