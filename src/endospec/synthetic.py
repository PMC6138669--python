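"""Synthetic fixtures: color checkers, tissue spectra, cameras and scenes.

Clinical endoscopic images of esophageal neoplasia are not publicly
deposited, so the pipeline is exercised on synthetic stand-ins that
reproduce the qualitative structure of the real data:

* tissue reflectance spectra whose class means obey the observed
  modality trends — white-light reflectivity strictly *decreasing* with
  severity (normal > dysplasia > dysplasia-ECA > ECA), Lugol iodine
  staining strictly *increasing* (unstained neoplasia is brighter than
  brown-stained normal mucosa), and NBI IPCL classes separated in mean;
* endoscopic-like scenes with curvilinear, darker intraepithelial
  papillary capillary loop (IPCL) strokes on a mucosa background, with
  a ground-truth vessel mask;
* a synthetic three-channel camera (Gaussian spectral sensitivities,
  sRGB output) standing in for the endoscope's sensor and xenon lamp.

Everything is seeded and bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .calibration import srgb_encode, xyz_from_spectrum
from .spectra import DEFAULT_WAVELENGTHS, check_same_grid, illuminant

__all__ = [
    "WHITE_LIGHT_STAGES",
    "IPCL_STAGES",
    "CameraModel",
    "SpectralScene",
    "default_camera",
    "make_color_checker",
    "make_tissue_spectrum",
    "make_endoscopic_scene",
    "render_rgb",
]

#: Lesion severity classes for white-light / Lugol modalities, mild to severe.
WHITE_LIGHT_STAGES = ("normal", "dysplasia", "dysplasia_ECA", "ECA")

#: IPCL morphology classes for NBI, mild to severe.
IPCL_STAGES = ("IPCL_IV", "IPCL_V1_HGD", "IPCL_V1_SCC", "IPCL_V3_SCC")

_MODALITIES = ("white_light", "lugol", "nbi")


@dataclass
class CameraModel:
    """A simple linear three-channel camera with sRGB output encoding.

    ``sensitivities`` holds the R, G, B spectral response curves (rows)
    on ``wavelengths``; ``illuminant_spd`` the scene illuminant.  The
    white point is the XYZ of a perfect reflector under that illuminant.
    Rendering normalizes each channel so a unit reflector maps to
    linear 1.0 (exposure normalization), hence encoded (255,255,255).
    """

    wavelengths: np.ndarray
    sensitivities: np.ndarray  # (3, n_wavelengths), non-negative
    illuminant_spd: np.ndarray
    srgb_output: bool = True
    white_point: np.ndarray = field(init=False)

    def __post_init__(self):
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.sensitivities = np.asarray(self.sensitivities, dtype=float)
        self.illuminant_spd = np.asarray(self.illuminant_spd, dtype=float)
        if np.any(self.sensitivities < 0):
            raise ValueError("spectral sensitivities must be non-negative")
        if self.sensitivities.shape != (3, self.wavelengths.size):
            raise ValueError("sensitivities must be (3, n_wavelengths)")
        if self.illuminant_spd.shape != self.wavelengths.shape:
            raise ValueError("illuminant grid mismatch")
        self.white_point = xyz_from_spectrum(
            np.ones_like(self.wavelengths),
            self.illuminant_spd,
            wavelengths=self.wavelengths,
        )


def default_camera(
    wavelengths: np.ndarray | None = None, illuminant_name: str = "flat"
) -> CameraModel:
    """The package's default synthetic endoscope camera.

    Narrow Gaussian bands (peaks 455/540/615 nm, sigma 20 nm).  Narrow,
    well-separated bands keep the channel-to-spectral-coefficient map
    well-conditioned, so calibration is limited by sensor quantization
    rather than by channel cross-talk.
    """
    wl = DEFAULT_WAVELENGTHS if wavelengths is None else np.asarray(wavelengths, float)
    peaks = (615.0, 540.0, 455.0)  # R, G, B
    sens = np.stack([np.exp(-0.5 * ((wl - p) / 20.0) ** 2) for p in peaks])
    return CameraModel(wl, sens, illuminant(illuminant_name, wl))


@dataclass
class SpectralScene:
    """Per-pixel ground-truth reflectance with labels and vessel mask."""

    reflectance: np.ndarray  # (H, W, n_wavelengths), values in [0, 1]
    wavelengths: np.ndarray
    stage_label: str
    modality: str
    vessel_mask: np.ndarray  # (H, W) bool

    def __post_init__(self):
        if self.vessel_mask.shape != self.reflectance.shape[:2]:
            raise ValueError("vessel_mask shape must match image shape")
        if self.reflectance.min() < 0 or self.reflectance.max() > 1:
            raise ValueError("reflectance must lie in [0, 1]")


def _smooth_bumps(wl: np.ndarray, centers, widths, weights) -> np.ndarray:
    out = np.zeros_like(wl)
    for c, w, a in zip(centers, widths, weights):
        out = out + a * np.exp(-0.5 * ((wl - c) / w) ** 2)
    return out


# amplitude scale per severity index 0..3; margins are large relative to
# the sigma=0.01 additive noise so orderings are strict in every draw
_WL_AMPLITUDE = (0.78, 0.62, 0.46, 0.30)
_LUGOL_AMPLITUDE = (0.22, 0.38, 0.54, 0.70)
_NBI_AMPLITUDE = {  # overall reflectivity declines with canceration degree
    "normal": 0.75,
    "IPCL_IV": 0.62,
    "IPCL_V1_HGD": 0.52,
    "IPCL_V1_SCC": 0.42,
    "IPCL_V3_SCC": 0.32,
}
# per-IPCL-stage weights of the ~415 / ~540 nm NBI bands: shifts the
# spectral shape so the classes also separate in PC-score space
_NBI_BAND_WEIGHTS = {
    "normal": (0.50, 0.50),
    "IPCL_IV": (0.60, 0.40),
    "IPCL_V1_HGD": (0.45, 0.55),
    "IPCL_V1_SCC": (0.65, 0.35),
    "IPCL_V3_SCC": (0.40, 0.60),
}


def make_tissue_spectrum(
    stage: str,
    modality: str = "white_light",
    seed: int = 0,
    wavelengths: np.ndarray | None = None,
    noise_sigma: float = 0.01,
) -> np.ndarray:
    """One noisy reflectance spectrum for a tissue class and modality.

    Spectra are smooth Gaussian-bump mixtures with a severity-scaled
    amplitude plus i.i.d. Gaussian noise (default sigma 0.01), clipped
    to [0, 1].  Smoothness keeps the family inside a low-dimensional
    principal-component span, as real mucosal reflectances are.
    """
    wl = DEFAULT_WAVELENGTHS if wavelengths is None else np.asarray(wavelengths, float)
    if modality not in _MODALITIES:
        raise ValueError(f"unknown modality {stage!r}; expected one of {_MODALITIES}")
    rng = np.random.default_rng(seed)

    if modality in ("white_light", "lugol"):
        if stage not in WHITE_LIGHT_STAGES:
            raise ValueError(
                f"unknown stage {stage!r} for {modality}; expected {WHITE_LIGHT_STAGES}"
            )
        s = WHITE_LIGHT_STAGES.index(stage)
        amp = _WL_AMPLITUDE[s] if modality == "white_light" else _LUGOL_AMPLITUDE[s]
        # mucosa-like shape: rising toward red with green/blue shoulders
        shape = _smooth_bumps(wl, (460, 550, 650), (55, 60, 90), (0.35, 0.55, 0.95))
    else:
        if stage not in IPCL_STAGES and stage != "normal":
            raise ValueError(
                f"unknown stage {stage!r} for nbi; expected {IPCL_STAGES} or 'normal'"
            )
        amp = _NBI_AMPLITUDE[stage]
        w415, w540 = _NBI_BAND_WEIGHTS[stage]
        shape = _smooth_bumps(
            wl, (415, 540, 640), (35, 45, 80), (1.1 * w415, 1.1 * w540, 0.30)
        )
    shape = shape / shape.max()
    jitter = 1.0 + 0.03 * rng.standard_normal()  # per-draw amplitude jitter
    spec = amp * jitter * shape + noise_sigma * rng.standard_normal(wl.size)
    return np.clip(spec, 0.0, 1.0)


def make_color_checker(
    n_patches: int = 30,
    seed: int = 0,
    wavelengths: np.ndarray | None = None,
    rank: int | None = None,
) -> np.ndarray:
    """Reflectance spectra of a synthetic color checker.

    Patches are random non-negative mixtures of eight smooth Gaussian
    bumps spanning the visible range, squashed into [0.02, 0.98]; with
    decaying mode weights the family is dominated by a few principal
    components, as real matte checkers are.

    Parameters
    ----------
    n_patches : int
        Number of patches (>= 4; 30 mirrors the standard mini checker).
    rank : int or None
        If given, draw instead from an exactly ``rank``-dimensional
        affine family (fixed base level plus ``rank`` smooth modes with
        bounded weights, so no clipping ever occurs).  Used for
        exact-recovery studies where the spectra must lie strictly in a
        low-dimensional subspace.

    Returns
    -------
    ndarray, shape (n_patches, n_wavelengths)
    """
    if n_patches < 4:
        raise ValueError(
            "n_patches must be >= 4: fewer patches leave the calibration "
            "regression underdetermined"
        )
    wl = DEFAULT_WAVELENGTHS if wavelengths is None else np.asarray(wavelengths, float)
    rng = np.random.default_rng(seed)
    if rank is not None:
        if not 1 <= rank <= 8:
            raise ValueError("rank must be in [1, 8]")
        centers = np.linspace(430, 680, rank) if rank > 1 else np.array([550.0])
        modes = np.stack([np.exp(-0.5 * ((wl - c) / 50.0) ** 2) for c in centers])
        # |weights| sum to <= 0.45 and modes <= 1, so spectra stay in
        # [0, 0.9] deterministically -- the family is exactly affine
        weights = rng.uniform(-1.0, 1.0, size=(n_patches, rank)) * (0.45 / rank)
        return 0.45 + weights @ modes
    centers = np.linspace(400, 760, 8)
    modes = np.stack([np.exp(-0.5 * ((wl - c) / 45.0) ** 2) for c in centers])
    scales = np.array([0.30, 0.28, 0.26, 0.10, 0.06, 0.04, 0.02, 0.01])
    weights = rng.standard_normal((n_patches, 8)) * scales
    base = rng.uniform(0.2, 0.7, size=(n_patches, 1))
    return np.clip(base + weights @ modes, 0.02, 0.98)


#: Disjoint reference triangles for the four IPCL stages in (FPC, SPC)
#: space, used by the labeled score-cloud generator.
DEFAULT_STAGE_TRIANGLES = {
    "IPCL_V3_SCC": np.array([[-3.0, -1.0], [-2.0, -1.0], [-2.5, 0.0]]),
    "IPCL_V1_SCC": np.array([[-1.5, 0.5], [-0.5, 0.5], [-1.0, 1.5]]),
    "IPCL_V1_HGD": np.array([[0.0, -1.5], [1.0, -1.5], [0.5, -0.5]]),
    "IPCL_IV": np.array([[1.5, 0.5], [2.5, 0.5], [2.0, 1.5]]),
}


def make_score_cloud(
    triangles: dict | None = None,
    n_per_class: int = 500,
    seed: int = 0,
    include_vertices: bool = True,
):
    """Labeled synthetic PC-score clouds, one uniform cloud per stage triangle.

    Points are drawn uniformly inside each stage's triangle by
    barycentric sampling.  With ``include_vertices`` (default) the three
    triangle corners are part of each class's sample — the synthetic
    analogue of hand-picking peripheral points — so the maximum-area
    triangle of the sample recovers the generating triangle exactly.

    Returns
    -------
    scores : ndarray (n_total, 2)
    labels : ndarray (n_total,) of stage strings
    """
    triangles = DEFAULT_STAGE_TRIANGLES if triangles is None else triangles
    rng = np.random.default_rng(seed)
    all_scores, all_labels = [], []
    for stage, verts in triangles.items():
        v = np.asarray(verts, dtype=float)
        n_inner = n_per_class - (3 if include_vertices else 0)
        if n_inner < 0:
            raise ValueError("n_per_class must be at least 3 with include_vertices")
        u = rng.uniform(size=(n_inner, 2))
        flip = u.sum(axis=1) > 1
        u[flip] = 1.0 - u[flip]
        pts = v[0] + u[:, :1] * (v[1] - v[0]) + u[:, 1:] * (v[2] - v[0])
        if include_vertices:
            pts = np.vstack([v, pts])
        all_scores.append(pts)
        all_labels.extend([stage] * len(pts))
    return np.vstack(all_scores), np.array(all_labels)


def _draw_stroke(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    """One curvilinear vessel stroke: a self-avoiding-ish random walk."""
    h, w = shape
    mask = np.zeros(shape, dtype=bool)
    r = rng.integers(h // 8, h - h // 8)
    c = rng.integers(w // 8, w - w // 8)
    angle = rng.uniform(0, 2 * np.pi)
    n_steps = int(rng.integers(30, 90))
    for _ in range(n_steps):
        mask[r, c] = True
        angle += rng.normal(0, 0.35)  # momentum keeps strokes curvilinear
        r = int(np.clip(round(r + np.sin(angle)), 1, h - 2))
        c = int(np.clip(round(c + np.cos(angle)), 1, w - 2))
    width = int(rng.integers(1, 4))
    if width > 1:
        mask = ndimage.binary_dilation(mask, iterations=width - 1)
    return mask


def make_endoscopic_scene(
    stage: str,
    modality: str = "nbi",
    size: tuple[int, int] = (256, 256),
    seed: int = 0,
    wavelengths: np.ndarray | None = None,
    n_strokes: int | None = None,
) -> SpectralScene:
    """A labeled spectral scene: mucosa background, optional IPCL strokes.

    For NBI with an IPCL stage, dark curvilinear strokes (width 1-3 px)
    are drawn and recorded in ``vessel_mask``; other modalities get an
    empty mask.  By default the stroke count is drawn uniformly from
    5-20; pass ``n_strokes`` to control vessel density explicitly (e.g.
    densely vascularized fields).  The background reflectance is the
    class spectrum modulated by smooth +/-5% spatial shading.
    """
    h, w = size
    if h < 64 or w < 64:
        raise ValueError("scene size must be at least 64x64")
    wl = DEFAULT_WAVELENGTHS if wavelengths is None else np.asarray(wavelengths, float)
    rng = np.random.default_rng(seed)

    base = make_tissue_spectrum(
        stage, modality, seed=int(rng.integers(2 ** 31)), wavelengths=wl
    )
    shading = ndimage.gaussian_filter(rng.standard_normal((h, w)), sigma=16)
    shading = 1.0 + 0.05 * shading / max(np.abs(shading).max(), 1e-12)

    refl = shading[..., None] * base[None, None, :]

    vessel_mask = np.zeros((h, w), dtype=bool)
    if modality == "nbi" and stage in IPCL_STAGES:
        count = int(rng.integers(5, 21)) if n_strokes is None else int(n_strokes)
        for _ in range(count):
            vessel_mask |= _draw_stroke(rng, (h, w))
        # vessels: strongly absorbing (hemoglobin) — much darker than mucosa
        refl = np.where(vessel_mask[..., None], 0.30 * refl, refl)

    refl = np.clip(refl, 0.0, 1.0).astype(np.float32)
    return SpectralScene(refl, wl, stage, modality, vessel_mask)


def render_rgb(
    scene, camera: CameraModel, quantize: bool = True
) -> np.ndarray:
    """Render reflectance through the camera to an sRGB image.

    Per pixel and channel the linear value is
    ``sum(reflectance * illuminant * sensitivity)``, normalized so a
    unit reflector maps to exactly 1.0, then sRGB-encoded.  With
    ``quantize=True`` (default) the result is 8-bit; otherwise the
    continuous encoded values on the 0-255 scale are returned, which is
    useful for quantization-free calibration studies.

    ``scene`` may be a :class:`SpectralScene` or a bare reflectance
    array ``(..., n_wavelengths)`` on the camera's grid.
    """
    if isinstance(scene, SpectralScene):
        check_same_grid(scene.wavelengths, camera.wavelengths)
        refl = scene.reflectance
    else:
        refl = np.asarray(scene, dtype=float)
        if refl.shape[-1] != camera.wavelengths.size:
            raise ValueError(
                "wavelength grid mismatch: scene has "
                f"{refl.shape[-1]} samples, camera {camera.wavelengths.size}"
            )
    weighted = camera.illuminant_spd * camera.sensitivities  # (3, n_wl)
    norm = weighted.sum(axis=1)  # unit reflector -> 1.0 per channel
    linear = refl @ (weighted / norm[:, None]).T
    encoded = srgb_encode(linear) if camera.srgb_output else np.clip(linear, 0, 1)
    scaled = encoded * 255.0
    return np.round(scaled).astype(np.uint8) if quantize else scaled
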