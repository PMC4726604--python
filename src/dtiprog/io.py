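"""File formats: NIfTI volumes, FSL bval/bvec tables, CSV with
provenance headers, YAML configs."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .tensor import ScalarVolume

__all__ = [
    "save_volume",
    "load_volume",
    "save_scalar_volume",
    "load_scalar_volume",
    "save_gradients",
    "load_gradients",
    "write_table",
    "read_table",
    "load_yaml",
    "dump_yaml",
]


def _affine(spacing) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def save_volume(path, data: np.ndarray, spacing=(2.5, 2.5, 2.5),
                dtype=np.float32) -> None:
    img = nib.Nifti1Image(np.asarray(data, dtype=dtype), _affine(spacing))
    img.header.set_zooms(tuple(spacing) + img.header.get_zooms()[3:])
    nib.save(img, str(path))


def load_volume(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=np.float64)
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, zooms


def save_scalar_volume(path, vol: ScalarVolume) -> None:
    save_volume(path, vol.data, vol.spacing)


def load_scalar_volume(path, measure: str) -> ScalarVolume:
    data, zooms = load_volume(path)
    return ScalarVolume(data, measure, zooms)


def save_gradients(prefix, bvals: np.ndarray, bvecs: np.ndarray) -> None:
    """Write ``<prefix>.bval`` / ``<prefix>.bvec`` in FSL convention
    (one row of b-values; three rows of gradient components)."""
    prefix = Path(prefix)
    np.savetxt(prefix.with_suffix(".bval"), bvals[None, :], fmt="%g")
    np.savetxt(prefix.with_suffix(".bvec"), np.asarray(bvecs).T, fmt="%.8f")


def load_gradients(prefix) -> tuple[np.ndarray, np.ndarray]:
    prefix = Path(prefix)
    bvals = np.loadtxt(prefix.with_suffix(".bval")).ravel()
    bvecs = np.loadtxt(prefix.with_suffix(".bvec"))
    if bvecs.shape[0] == 3:
        bvecs = bvecs.T
    return bvals, bvecs


def write_table(path, df: pd.DataFrame, *, seed: "int | None" = None,
                extra: "Mapping[str, object] | None" = None) -> None:
    """CSV with a commented provenance header (tool version, seed)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# dtiprog {__version__}\n")
        if seed is not None:
            fh.write(f"# seed: {seed}\n")
        for k, v in (extra or {}).items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def load_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def dump_yaml(path, obj) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)
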