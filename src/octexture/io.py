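"""On-disk cohort layout: one numeric-array file per eye plus a manifest.

Volumes and surfaces are stored as plain ``.npy`` arrays (no proprietary
scanner formats); the manifest is a CSV with one row per eye.  This is
also the entry point for real data: any volume + surface arrays matching
the documented axis conventions can be listed in a manifest and fed to
the pipeline.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from .synth import EyeRecord, LayerSurfaces, OCTVolume

MANIFEST_NAME = "manifest.csv"


def save_cohort(directory: str | Path, eyes: Iterable[EyeRecord],
                seed: int | None = None) -> Path:
    """Write every eye's volume + surfaces and the manifest; returns the
    manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for eye in eyes:
        eye_id = f"{eye.subject_id}_{eye.laterality[0].upper()}"
        vol_path = directory / f"{eye_id}_volume.npy"
        surf_path = directory / f"{eye_id}_surfaces.npy"
        np.save(vol_path, eye.volume.intensity.astype(np.float32))
        np.save(surf_path, eye.surfaces.depths.astype(np.float32))
        sx, sy, sz = eye.volume.voxel_scale
        rows.append({
            "eye_id": eye_id, "subject_id": eye.subject_id,
            "laterality": eye.laterality, "class": eye.class_label,
            "volume_path": vol_path.name, "surfaces_path": surf_path.name,
            "scale_x_um": sx, "scale_y_um": sy, "scale_z_um": sz,
            "seed": seed if seed is not None else "",
        })
    manifest = directory / MANIFEST_NAME
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def load_cohort(directory: str | Path) -> Iterator[EyeRecord]:
    """Stream EyeRecords back from a manifest directory."""
    directory = Path(directory)
    manifest = pd.read_csv(directory / MANIFEST_NAME)
    for _, row in manifest.iterrows():
        vol = np.load(directory / row["volume_path"]).astype(float)
        surf = np.load(directory / row["surfaces_path"]).astype(float)
        volume = OCTVolume(
            vol,
            (row["scale_x_um"], row["scale_y_um"], row["scale_z_um"]),
            row["laterality"],
        )
        yield EyeRecord(row["subject_id"], row["laterality"], row["class"],
                        volume, LayerSurfaces(surf))
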