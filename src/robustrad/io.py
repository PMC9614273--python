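"""Reading and writing volumes, results and run manifests.

Volumes are NIfTI (.nii / .nii.gz) via nibabel; voxel spacing is taken from
the affine.  Results are tidy CSV plus a JSON summary and a run manifest
holding the configuration hash, seeds and package version, which suffices to
replay a run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .types import GridMismatchError, ImageVolume, Mask

__all__ = [
    "read_volume_pair",
    "write_volume",
    "write_cohort",
    "write_results",
    "config_hash",
    "load_run_config",
]


def _from_nifti(path: str | Path) -> tuple[np.ndarray, tuple, tuple]:
    img = nib.load(str(path))
    arr = np.asarray(img.dataobj, dtype=float)
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D volume, got {arr.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return arr, spacing, origin


def read_volume_pair(image_path: str | Path,
                     mask_path: str | Path) -> tuple[ImageVolume, Mask]:
    """Read an image/mask NIfTI pair; the mask is binarized at > 0.

    Raises :class:`GridMismatchError` when shapes or spacings disagree.
    """
    for p in (image_path, mask_path):
        name = Path(p).name
        if not (name.endswith(".nii") or name.endswith(".nii.gz")):
            raise ValueError(f"unsupported format: {p} (NIfTI only)")
    arr_i, sp_i, or_i = _from_nifti(image_path)
    arr_m, sp_m, or_m = _from_nifti(mask_path)
    image = ImageVolume(arr_i, sp_i, or_i)
    mask = Mask(arr_m > 0, sp_m, or_m)
    image.require_same_grid(mask)
    return image, mask


def write_volume(volume: ImageVolume, path: str | Path) -> Path:
    """Write a volume (or mask) as NIfTI, spacing on the affine diagonal."""
    affine = np.diag(list(volume.spacing) + [1.0])
    affine[:3, 3] = volume.origin
    arr = np.asarray(volume.array)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    nib.save(nib.Nifti1Image(arr, affine), str(path))
    return Path(path)


def write_cohort(cohort, out_dir: str | Path) -> Path:
    """Write a phantom cohort: NIfTI volumes, outcomes CSV, manifest JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for p in cohort.patients:
        img_path = out / f"{p.id}_image.nii.gz"
        msk_path = out / f"{p.id}_mask.nii.gz"
        write_volume(p.image, img_path)
        write_volume(p.mask, msk_path)
        entries.append({"id": p.id, "image": img_path.name,
                        "mask": msk_path.name})
    cohort.outcomes.rename_axis("id").to_csv(out / "outcomes.csv")
    manifest = {"patients": entries, "truth": cohort.truth}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out / "manifest.json"


def config_hash(config) -> str:
    """Stable hash of a configuration object (dataclass, dict or mapping)."""
    if dataclasses.is_dataclass(config) and not isinstance(config, type):
        payload = dataclasses.asdict(config)
    else:
        payload = dict(config)
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_results(records: pd.DataFrame, comparisons: pd.DataFrame,
                  out_dir: str | Path, config=None, seed: int | None = None
                  ) -> Path:
    """Write experiment results: records CSV, comparisons JSON, manifest.

    Overwrites existing files (idempotent); raises on empty records.
    """
    if records is None or len(records) == 0:
        raise ValueError("no records to write")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records.to_csv(out / "records.csv", index=False)
    comparisons.to_json(out / "comparisons.json", orient="records", indent=2)
    from importlib.metadata import PackageNotFoundError, version
    try:
        pkg_version = version("robustrad")
    except PackageNotFoundError:
        pkg_version = "unknown"
    manifest = {
        "n_records": int(len(records)),
        "config_hash": config_hash(config) if config is not None else None,
        "seed": seed,
        "package_version": pkg_version,
    }
    path = out / "run_manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path


def load_run_config(path: str | Path) -> dict:
    """Load a YAML run configuration into a plain dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("run configuration must be a mapping")
    return cfg
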