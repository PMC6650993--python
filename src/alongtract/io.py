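"""File formats: NIfTI volumes, affine text matrices, cohort manifests, RT CSVs."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .skeleton import TractVolume

__all__ = [
    "CohortManifest",
    "read_volume",
    "write_volume",
    "read_affine",
    "write_affine",
    "read_manifest",
    "read_rt_csv",
    "write_json",
]

_VOLUME_COLUMNS = ("tract_prob", "NDI", "ODI", "FA", "MD", "wm_mask")
_MANIFEST_COLUMNS = ("participant", "age") + _VOLUME_COLUMNS + ("affine", "rt_file")


def read_volume(path, threshold: float | None = None) -> TractVolume:
    img = nib.load(str(path))
    return TractVolume(np.asarray(img.dataobj, dtype=np.float64), img.affine,
                       threshold=threshold)


def write_volume(vol_or_data, path, affine: np.ndarray | None = None) -> None:
    if isinstance(vol_or_data, TractVolume):
        data, affine = vol_or_data.data, vol_or_data.affine
    else:
        data = vol_or_data
        if affine is None:
            raise ValueError("affine required when writing a bare array")
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine), str(path))


def read_affine(path) -> np.ndarray:
    mat = np.loadtxt(str(path))
    if mat.shape != (4, 4):
        raise ValueError(f"{path}: expected a 4x4 whitespace-delimited matrix")
    if abs(np.linalg.det(mat[:3, :3])) < 1e-12:
        raise ValueError(f"{path}: affine is not invertible")
    return mat


def write_affine(mat: np.ndarray, path) -> None:
    np.savetxt(str(path), np.asarray(mat, dtype=float), fmt="%.10g")


def read_rt_csv(path) -> np.ndarray:
    """RTs in ms from a single-participant CSV with an ``rt_ms`` column."""
    df = pd.read_csv(path)
    if "rt_ms" not in df.columns:
        raise ValueError(f"{path}: missing 'rt_ms' column")
    return df["rt_ms"].to_numpy(dtype=float)


@dataclass
class CohortManifest:
    """Validated table of per-participant file paths and covariates."""

    table: pd.DataFrame
    root: Path

    @property
    def participants(self) -> list[str]:
        return list(self.table["participant"])

    def path(self, participant: str, column: str) -> Path:
        row = self.table.loc[self.table["participant"] == participant].iloc[0]
        return self.root / str(row[column])


def read_manifest(path) -> CohortManifest:
    path = Path(path)
    table = pd.read_csv(path, sep="\t")
    missing_cols = [c for c in _MANIFEST_COLUMNS if c not in table.columns]
    if missing_cols:
        raise ValueError(f"manifest missing columns: {missing_cols}")
    if table["participant"].duplicated().any():
        dups = table.loc[table["participant"].duplicated(), "participant"].tolist()
        raise ValueError(f"duplicate participant ids: {dups}")
    if not np.issubdtype(table["age"].dtype, np.number):
        raise ValueError("ages must be numeric")
    root = path.parent
    for _, row in table.iterrows():
        for col in _VOLUME_COLUMNS + ("affine", "rt_file"):
            p = root / str(row[col])
            if not p.exists():
                raise FileNotFoundError(
                    f"manifest row '{row['participant']}': missing file {p} ({col})"
                )
    return CohortManifest(table=table, root=root)


def write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default, allow_nan=True))
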