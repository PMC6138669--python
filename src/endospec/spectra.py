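"""Wavelength grids, observer functions and illuminants.

Reflectance spectra throughout the package are plain 1-D numpy arrays
sampled on a shared wavelength grid, by default the visible range
380-780 nm at 5 nm spacing (81 samples).  All radiometric quantities
are relative (reflectance in [0, 1], illuminants normalized at 560 nm);
the package makes no absolute-radiometry claims.
"""

from __future__ import annotations

import numpy as np

#: Default wavelength grid, nm: 380-780 at 5 nm (81 samples).
DEFAULT_WAVELENGTHS = np.arange(380.0, 781.0, 5.0)


def check_same_grid(*grids: np.ndarray) -> np.ndarray:
    """Verify that all wavelength grids are identical; return the grid.

    Raises
    ------
    ValueError
        If any two grids differ in length or values.
    """
    ref = np.asarray(grids[0], dtype=float)
    for g in grids[1:]:
        g = np.asarray(g, dtype=float)
        if g.shape != ref.shape or not np.allclose(g, ref):
            raise ValueError(
                "wavelength grid mismatch: "
                f"{ref.shape}/{ref[0]}-{ref[-1]} vs {g.shape}/{g[0]}-{g[-1]}"
            )
    return ref


def _gauss_piecewise(x: np.ndarray, mu: float, s1: float, s2: float) -> np.ndarray:
    # asymmetric Gaussian lobe: different sigma on each side of the peak
    s = np.where(x < mu, s1, s2)
    return np.exp(-0.5 * ((x - mu) / s) ** 2)


def cie_1931_cmfs(wavelengths: np.ndarray | None = None) -> np.ndarray:
    """CIE 1931 2-degree color-matching functions on a wavelength grid.

    Uses the multi-lobe asymmetric-Gaussian analytic fit of Wyman, Sloan
    & Shirley (JCGT 2013), accurate to a few parts per thousand across
    the visible range — ample for colorimetric calibration of synthetic
    cameras.

    Returns
    -------
    ndarray, shape (n_wavelengths, 3)
        Columns are x-bar, y-bar, z-bar.
    """
    wl = DEFAULT_WAVELENGTHS if wavelengths is None else np.asarray(wavelengths, float)
    x = (
        1.056 * _gauss_piecewise(wl, 599.8, 37.9, 31.0)
        + 0.362 * _gauss_piecewise(wl, 442.0, 16.0, 26.7)
        - 0.065 * _gauss_piecewise(wl, 501.1, 20.4, 26.2)
    )
    y = 0.821 * _gauss_piecewise(wl, 568.8, 46.9, 40.5) + 0.286 * _gauss_piecewise(
        wl, 530.9, 16.3, 31.1
    )
    z = 1.217 * _gauss_piecewise(wl, 437.0, 11.8, 36.0) + 0.681 * _gauss_piecewise(
        wl, 459.0, 26.0, 13.8
    )
    return np.stack([x, y, z], axis=1)


def illuminant(name: str = "flat", wavelengths: np.ndarray | None = None) -> np.ndarray:
    """Relative spectral power of a named illuminant.

    ``"flat"`` is an equal-energy stand-in for the broadband xenon lamp
    of an endoscope light source.  ``"daylight"`` is a Planckian
    radiator at 6504 K, a smooth daylight-like spectrum with a genuinely
    different white point, used for color-checker measurement so that
    chromatic adaptation is exercised with distinct whites.

    All illuminants are normalized to 1.0 at 560 nm.
    """
    wl = DEFAULT_WAVELENGTHS if wavelengths is None else np.asarray(wavelengths, float)
    if name == "flat":
        return np.ones_like(wl)
    if name == "daylight":
        # Planck's law at T = 6504 K, wavelength in metres
        t = 6504.0
        lam = wl * 1e-9
        c2 = 1.4388e-2  # m K
        power = lam ** -5 / np.expm1(c2 / (lam * t))
        ref = (560e-9) ** -5 / np.expm1(c2 / (560e-9 * t))
        return power / ref
    raise ValueError(f"unknown illuminant {name!r}; expected 'flat' or 'daylight'")
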