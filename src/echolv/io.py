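"""File formats: cine stacks (TIFF/NIfTI + JSON sidecar), anchor CSV, models.

Cine stacks are written as multi-page TIFF (pages ordered t-major, one page
per (t, z)) or as 4D NIfTI; either carries a JSON sidecar with the spatial
and temporal metadata.  Anchor radii use a tidy CSV dialect with columns
``animal_id, frame, cycle_phase, theta_deg, boundary, z_frac, radius_mm``.
Fitted models are stored as a single ``.npz`` container with a JSON metadata
entry.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import geometry
from .models import BoundaryRegressor
from .features import ImageBasis, ImagePCA, TimeBasis
from .phantom import CineDataset

SIDECAR_SUFFIX = ".json"


def _sidecar(dataset: CineDataset) -> dict:
    return {
        "animal_id": dataset.animal_id,
        "pixel_spacing_mm": dataset.pixel_spacing,
        "slice_spacing_mm": dataset.slice_spacing,
        "slice_origin_z_mm": dataset.slice_origin_z,
        "cycle_phase": dataset.cycle_phase.tolist(),
        "apex_z": dataset.apex_z.tolist(),
        "base_z": dataset.base_z.tolist(),
        "cycle_duration_s": dataset.cycle_duration_s,
        "shape_tzyx": list(dataset.intensities.shape),
    }


def save_cine(dataset: CineDataset, path_base: str | Path, fmt: str = "tiff") -> Path:
    """Write a cine dataset plus its JSON sidecar; returns the image path."""
    path_base = Path(path_base)
    path_base.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "tiff":
        import tifffile

        img_path = path_base.with_suffix(".tif")
        t, z, y, x = dataset.intensities.shape
        tifffile.imwrite(img_path, dataset.intensities.reshape(t * z, y, x))
    elif fmt == "nifti":
        import nibabel as nib

        img_path = path_base.with_suffix(".nii")
        # NIfTI axis order (x, y, z, t)
        data = np.transpose(dataset.intensities, (3, 2, 1, 0))
        affine = np.diag([dataset.pixel_spacing, dataset.pixel_spacing,
                          dataset.slice_spacing, 1.0])
        nib.save(nib.Nifti1Image(data, affine), img_path)
    else:
        raise ValueError(f"unknown cine format {fmt!r}")
    with open(path_base.with_suffix(SIDECAR_SUFFIX), "w") as fh:
        json.dump(_sidecar(dataset), fh, indent=1)
    return img_path


def load_cine(path_base: str | Path) -> CineDataset:
    """Load a cine dataset written by :func:`save_cine` (either format)."""
    path_base = Path(path_base)
    with open(path_base.with_suffix(SIDECAR_SUFFIX)) as fh:
        meta = json.load(fh)
    shape = tuple(meta["shape_tzyx"])
    tif = path_base.with_suffix(".tif")
    nii = path_base.with_suffix(".nii")
    if tif.exists():
        import tifffile

        data = tifffile.imread(tif).reshape(shape)
    elif nii.exists():
        import nibabel as nib

        data = np.transpose(np.asarray(nib.load(nii).dataobj), (3, 2, 1, 0))
    else:
        raise FileNotFoundError(f"no cine image found for {path_base} (.tif or .nii)")
    return CineDataset(
        intensities=np.asarray(data, dtype=np.float32),
        pixel_spacing=meta["pixel_spacing_mm"],
        slice_spacing=meta["slice_spacing_mm"],
        slice_origin_z=meta["slice_origin_z_mm"],
        cycle_phase=np.array(meta["cycle_phase"]),
        apex_z=np.array(meta["apex_z"]),
        base_z=np.array(meta["base_z"]),
        animal_id=meta["animal_id"],
        cycle_duration_s=meta["cycle_duration_s"],
    )


# ---------------------------------------------------------------------------
# anchor radii


def anchor_radii_to_csv(radii_by_animal: dict[str, geometry.AnchorRadii],
                        path: str | Path) -> None:
    frames = [r.to_tidy(animal_id=a) for a, r in radii_by_animal.items()]
    df = pd.concat(frames, ignore_index=True)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.9g")


def anchor_radii_from_csv(path: str | Path,
                          validate: bool = True) -> dict[str, geometry.AnchorRadii]:
    df = pd.read_csv(path)
    out = {}
    for animal_id, sub in df.groupby("animal_id", sort=True):
        frames = np.sort(sub["frame"].unique())
        piv = sub.pivot_table(index="frame",
                              columns=["z_frac", "boundary", "theta_deg"],
                              values="radius_mm", sort=True)
        # canonical anchor order: z asc, endo before epi, theta asc
        cols = [(a.z_frac, a.boundary, a.theta_deg) for a in geometry.anchor_grid()]
        values = piv[cols].to_numpy()
        phase = sub.drop_duplicates("frame").sort_values("frame")["cycle_phase"].to_numpy()
        out[str(animal_id)] = geometry.AnchorRadii(
            values=values, cycle_phase=phase, validate=validate
        )
    return out


# ---------------------------------------------------------------------------
# fitted bases and models


def save_image_basis(basis: ImageBasis, path: str | Path,
                     training_checksum: str | None = None) -> None:
    """Serialize a fitted PCA image basis to a single-file .npz container."""
    meta = {
        "scope": basis.scope,
        "k_max": basis.k_max,
        "image_shape": list(basis.image_shape),
        "n_slices": basis.n_slices,
        "training_checksum": training_checksum,
    }
    arrays = {"meta": np.array(json.dumps(meta))}
    for i, blk in enumerate(basis.blocks):
        arrays[f"mean_{i}"] = blk.mean_
        arrays[f"components_{i}"] = blk.components_
        arrays[f"explained_variance_{i}"] = blk.explained_variance_
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(path, **arrays)


def _load_pca_blocks(data) -> list[ImagePCA]:
    blocks = []
    i = 0
    while f"mean_{i}" in data:
        blk = ImagePCA(n_components=int(data[f"components_{i}"].shape[0]))
        blk.mean_ = data[f"mean_{i}"]
        blk.components_ = data[f"components_{i}"]
        blk.explained_variance_ = data[f"explained_variance_{i}"]
        blk.n_components_ = blk.components_.shape[0]
        blk.n_features_in_ = blk.components_.shape[1]
        blocks.append(blk)
        i += 1
    return blocks


def load_image_basis(path: str | Path) -> ImageBasis:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        blocks = _load_pca_blocks(data)
    return ImageBasis(scope=meta["scope"], blocks=blocks,
                      image_shape=tuple(meta["image_shape"]),
                      n_slices=meta["n_slices"])


def save_model(model: BoundaryRegressor, path: str | Path) -> None:
    """Serialize a fitted model to a single-file .npz container."""
    meta = {
        "variant": model.variant,
        "n_components": model.n_components_,
        "n_basis": model.n_basis,
        "periodic_time_basis": model.periodic_time_basis,
        "assist_anchor": {
            "theta_deg": model.assist_anchor.theta_deg,
            "boundary": model.assist_anchor.boundary,
            "z_frac": model.assist_anchor.z_frac,
        },
        "slice_fractions": list(model.slice_fractions),
        "scope": model.image_basis_.scope,
        "image_shape": list(model.image_basis_.image_shape),
        "n_slices": model.image_basis_.n_slices,
        "anchor_order": [
            [a.theta_deg, a.boundary, a.z_frac] for a in geometry.anchor_grid()
        ],
    }
    arrays = {"coef": model.coef_, "meta": np.array(json.dumps(meta))}
    for i, blk in enumerate(model.image_basis_.blocks):
        arrays[f"mean_{i}"] = blk.mean_
        arrays[f"components_{i}"] = blk.components_
        arrays[f"explained_variance_{i}"] = blk.explained_variance_
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(path, **arrays)


def load_model(path: str | Path) -> BoundaryRegressor:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        blocks = _load_pca_blocks(data)
        coef = data["coef"]
    aa = meta["assist_anchor"]
    model = BoundaryRegressor(
        variant=meta["variant"],
        n_components=meta["n_components"],
        n_basis=meta["n_basis"],
        periodic_time_basis=meta["periodic_time_basis"],
        assist_anchor=geometry.AnchorIndex(aa["theta_deg"], aa["boundary"], aa["z_frac"]),
        slice_fractions=tuple(meta["slice_fractions"]),
    )
    model.image_basis_ = ImageBasis(
        scope=meta["scope"], blocks=blocks,
        image_shape=tuple(meta["image_shape"]), n_slices=meta["n_slices"],
    )
    model.n_components_ = meta["n_components"]
    model.time_basis_ = TimeBasis(n_basis=meta["n_basis"],
                                  periodic=meta["periodic_time_basis"])
    model.coef_ = coef
    return model


# ---------------------------------------------------------------------------
# manifests


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path: str | Path, config: dict, seed: int,
                   artifacts: Sequence[str | Path]) -> None:
    from . import __version__

    payload = {
        "package_version": __version__,
        "seed": seed,
        "config": config,
        "artifacts": {str(p): sha256_of(p) for p in artifacts},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
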