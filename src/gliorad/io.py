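"""File formats: NIfTI volumes, TSV tables, YAML run configs.

Naming conventions on disk: channels ``{patient}_{channel}.nii.gz``, masks
``{patient}_voi_{core|edema}.nii.gz``, an optional shared ``atlas.nii.gz``.
Feature tables are TSV with a leading ``patient_id`` column, 489 feature
columns in catalog order, and ``NA`` for missing values; the catalog hash
is embedded as a ``# catalog_hash=...`` header line so tables and model
artifacts can be cross-checked at predict time.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .preprocess import RawChannel, VoiMask

HASH_HEADER = "# catalog_hash="


def write_nifti(path: str | Path, values: np.ndarray,
                spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> None:
    affine = np.diag([*spacing, 1.0])
    img = nib.Nifti1Image(np.asarray(values, dtype=np.float32), affine)
    nib.save(img, str(path))


def read_channel(path: str | Path, modality: str) -> RawChannel:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return RawChannel(values=np.asarray(img.dataobj, dtype=float),
                      spacing=spacing, modality=modality)


def read_mask(path: str | Path, label: str) -> VoiMask:
    img = nib.load(str(path))
    return VoiMask(mask=np.asarray(img.dataobj) > 0.5, label=label)


def read_atlas(path: str | Path) -> np.ndarray:
    return np.rint(np.asarray(nib.load(str(path)).dataobj)).astype(int)


def write_feature_table(path: str | Path, table: pd.DataFrame,
                        catalog_hash: str | None = None) -> None:
    path = Path(path)
    with path.open("w") as fh:
        if catalog_hash:
            fh.write(f"{HASH_HEADER}{catalog_hash}\n")
        table.to_csv(fh, sep="\t", index=False, na_rep="NA")


def read_feature_table(path: str | Path) -> tuple[pd.DataFrame, str | None]:
    path = Path(path)
    catalog_hash = None
    with path.open() as fh:
        first = fh.readline()
        if first.startswith(HASH_HEADER):
            catalog_hash = first[len(HASH_HEADER):].strip()
        else:
            fh.seek(0)
        df = pd.read_csv(fh, sep="\t", na_values=["NA"])
    return df, catalog_hash


def write_tsv(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])


def load_config(path: str | Path) -> dict:
    with Path(path).open() as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("run config must be a YAML mapping")
    return cfg


def save_config(path: str | Path, cfg: dict) -> None:
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=True))
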