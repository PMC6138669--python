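"""Serialization: model JSON, checker/coordinate CSV, cubes, scenes.

All outputs carry a ``provenance`` block (package version, config dict,
SHA-256 of the inputs); nothing time-varying is written, so re-running
a stage with unchanged inputs is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from . import __version__
from .calibration import FEATURE_ORDER
from .reconstruction import SpectralBasisPCA, SpectralReconstructor
from .segmentation import SkeletonCoordinates
from .staging import TriangleRegion
from .synthetic import SpectralScene


def sha256_of(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def provenance(config: dict | None = None, inputs: dict | None = None) -> dict:
    block = {"package": "endospec", "version": __version__}
    if config:
        block["config"] = config
    if inputs:
        block["input_sha256"] = {k: sha256_of(v) for k, v in inputs.items()}
    return block


def _dump_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------- checker CSV

def write_checker_csv(path, wavelengths, spectra) -> None:
    """Checker table: wavelength_nm column plus one column per patch."""
    spectra = np.asarray(spectra)
    cols = {"wavelength_nm": np.asarray(wavelengths)}
    for i, spec in enumerate(spectra):
        cols[f"patch_{i + 1:03d}"] = spec
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.10g")


def read_checker_csv(path):
    df = pd.read_csv(path)
    wl = df["wavelength_nm"].to_numpy(dtype=float)
    patches = [c for c in df.columns if c.startswith("patch_")]
    return wl, df[patches].to_numpy(dtype=float).T


def write_spectrum_csv(path, wavelengths, spectrum) -> None:
    pd.DataFrame(
        {"wavelength_nm": np.asarray(wavelengths), "reflectance": np.asarray(spectrum)}
    ).to_csv(path, index=False, float_format="%.10g")


def write_rgb_csv(path, rgbs) -> None:
    pd.DataFrame(np.asarray(rgbs), columns=["R", "G", "B"]).to_csv(
        path, index=False, float_format="%.10g"
    )


def read_rgb_csv(path):
    return pd.read_csv(path)[["R", "G", "B"]].to_numpy(dtype=float)


# -------------------------------------------------------------- model JSON

def save_reconstructor(path, model: SpectralReconstructor, prov: dict | None = None) -> None:
    obj = {
        "feature_order": list(FEATURE_ORDER),
        "n_components": int(model.n_components),
        "wavelengths": model.wavelengths_.tolist(),
        "basis_mean": model.basis_.mean_.tolist(),
        "basis_components": model.basis_.components_.tolist(),
        "explained_variance": model.basis_.explained_variance_.tolist(),
        "transformation_matrix": model.transformation_matrix_.tolist(),
        "residual_rmse": np.asarray(model.residual_rmse_).tolist(),
        "src_white": None if model.src_white is None else list(map(float, model.src_white)),
        "dst_white": None if model.dst_white is None else list(map(float, model.dst_white)),
        "clip_band": list(model.clip_band),
        "provenance": prov or provenance(),
    }
    _dump_json(obj, path)


def load_reconstructor(path) -> SpectralReconstructor:
    obj = json.loads(Path(path).read_text())
    if obj.get("feature_order") != list(FEATURE_ORDER):
        raise ValueError("model file uses an unknown feature ordering")
    comps = np.asarray(obj["basis_components"], dtype=float)
    k = int(obj["n_components"])
    tmat = np.asarray(obj["transformation_matrix"], dtype=float)
    if comps.shape[0] != k or tmat.shape != (k, 20):
        raise ValueError(
            f"dimension mismatch in model file: k={k}, components "
            f"{comps.shape}, transformation matrix {tmat.shape} (expected ({k}, 20))"
        )
    model = SpectralReconstructor(
        n_components=k,
        src_white=obj["src_white"],
        dst_white=obj["dst_white"],
        clip_band=tuple(obj["clip_band"]),
        wavelengths=np.asarray(obj["wavelengths"], dtype=float),
    )
    basis = SpectralBasisPCA(n_components=k)
    basis.mean_ = np.asarray(obj["basis_mean"], dtype=float)
    basis.components_ = comps
    basis.explained_variance_ = np.asarray(obj["explained_variance"], dtype=float)
    basis.n_features_in_ = comps.shape[1]
    model.basis_ = basis
    model.transformation_matrix_ = tmat
    model.residual_rmse_ = np.asarray(obj["residual_rmse"], dtype=float)
    model.wavelengths_ = np.asarray(obj["wavelengths"], dtype=float)
    model.last_clip_count_ = 0
    return model


# ------------------------------------------------------------ regions JSON

def save_regions(path, regions: dict, prov: dict | None = None) -> None:
    obj = {
        "regions": {s: r.vertices.tolist() for s, r in regions.items()},
        "provenance": prov or provenance(),
    }
    _dump_json(obj, path)


def load_regions(path) -> dict:
    obj = json.loads(Path(path).read_text())
    return {
        stage: TriangleRegion(np.asarray(v, dtype=float), stage)
        for stage, v in obj["regions"].items()
    }


# ------------------------------------------------------------- coordinates

def write_coordinates_csv(path, coords: SkeletonCoordinates) -> None:
    pd.DataFrame(coords.coords, columns=["row", "col"]).to_csv(path, index=False)


def read_coordinates_csv(path) -> np.ndarray:
    return pd.read_csv(path)[["row", "col"]].to_numpy(dtype=int)


# ------------------------------------------------------------------ images

def write_png(path, image: np.ndarray) -> None:
    Image.fromarray(np.asarray(image, dtype=np.uint8)).save(path, format="PNG")


def read_png(path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("RGB"))


# --------------------------------------------------------------- cubes/scenes

def save_cube(path_base, cube: np.ndarray, wavelengths, prov: dict | None = None) -> None:
    """Spectral cube: raw .npy array plus a .json sidecar header."""
    base = Path(path_base)
    np.save(base.with_suffix(".npy"), np.asarray(cube, dtype=np.float32))
    _dump_json(
        {
            "shape": list(cube.shape),
            "dtype": "float32",
            "wavelengths": np.asarray(wavelengths).tolist(),
            "provenance": prov or provenance(),
        },
        base.with_suffix(".json"),
    )


def load_cube(path_base):
    base = Path(path_base)
    header = json.loads(base.with_suffix(".json").read_text())
    cube = np.load(base.with_suffix(".npy"))
    return cube, np.asarray(header["wavelengths"], dtype=float), header


def save_scene(path_base, scene: SpectralScene, rgb: np.ndarray) -> None:
    """Scene bundle: rendered PNG, ground-truth sidecars, label JSON.

    Sidecars are plain ``.npy`` files (not a zip archive): ``.npy`` has
    no embedded timestamps, keeping seeded re-runs byte-identical.
    """
    base = Path(path_base)
    write_png(base.with_suffix(".png"), rgb)
    np.save(base.with_suffix(".reflectance.npy"), scene.reflectance)
    np.save(base.with_suffix(".vessel_mask.npy"), scene.vessel_mask)
    np.save(base.with_suffix(".wavelengths.npy"), scene.wavelengths)
    _dump_json(
        {
            "stage_label": scene.stage_label,
            "modality": scene.modality,
            "shape": list(scene.reflectance.shape),
            "provenance": provenance(),
        },
        base.with_suffix(".labels.json"),
    )


def load_scene(path_base) -> tuple[SpectralScene, np.ndarray]:
    base = Path(path_base)
    labels = json.loads(base.with_suffix(".labels.json").read_text())
    scene = SpectralScene(
        np.load(base.with_suffix(".reflectance.npy")),
        np.load(base.with_suffix(".wavelengths.npy")),
        labels["stage_label"],
        labels["modality"],
        np.load(base.with_suffix(".vessel_mask.npy")).astype(bool),
    )
    return scene, read_png(base.with_suffix(".png"))
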