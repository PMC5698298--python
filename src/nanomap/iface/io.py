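"""Reading and writing height images and measurement tables.

Height images are 32-bit float TIFF (heights in nm) or whitespace-delimited
ASCII matrices, each with a JSON sidecar carrying ``pixel_size_nm`` and
``origin_nm``. The pixel size is never guessed: a missing sidecar (and no
embedded scale) is an error.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from nanomap.imageproc import HeightImage

_ASCII_SUFFIXES = {".txt", ".asc", ".dat", ".mat"}


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_height_image(img: HeightImage, path, overwrite: bool = False) -> Path:
    """Write a height image as float32 TIFF (or ASCII matrix) + JSON sidecar."""
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not overwrite and (path.exists() or sidecar.exists()):
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace")
    if path.suffix.lower() in _ASCII_SUFFIXES:
        np.savetxt(path, img.heights, fmt="%.6g")
    else:
        tifffile.imwrite(path, img.heights.astype(np.float32))
    meta = {
        "pixel_size_nm": img.pixel_size_nm,
        "origin_nm": list(img.origin_nm),
        "metadata": {k: v for k, v in img.metadata.items() if _json_safe(v)},
    }
    sidecar.write_text(json.dumps(meta, indent=1, sort_keys=True))
    return path


def _json_safe(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False


def read_height_image(path) -> HeightImage:
    """Read a TIFF or ASCII height image; the JSON sidecar is mandatory."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise ValueError(
            f"no sidecar {sidecar.name}: pixel_size_nm is required and never guessed"
        )
    meta = json.loads(sidecar.read_text())
    if "pixel_size_nm" not in meta:
        raise ValueError(f"sidecar {sidecar} lacks pixel_size_nm")
    if path.suffix.lower() in _ASCII_SUFFIXES:
        heights = np.loadtxt(path, ndmin=2)
    else:
        heights = tifffile.imread(path)
    origin = tuple(meta.get("origin_nm", (0.0, 0.0)))
    return HeightImage(
        np.asarray(heights, dtype=float),
        float(meta["pixel_size_nm"]),
        origin,
        dict(meta.get("metadata", {})),
    )


MEASUREMENT_COLUMNS = [
    "molecule_id",
    "contour_nm",
    "contour_bp",
    "label_index",
    "arc_nm",
    "arc_bp",
    "prominence_nm",
    "flags",
]


def write_measurements_tsv(measurements, path, cal=None, overwrite: bool = False) -> Path:
    """Write molecule measurements as a TSV, one row per label (or one row
    with NA label fields for unlabeled molecules)."""
    from nanomap.calibration import Calibration

    cal = cal or Calibration()
    path = Path(path)
    if not overwrite and path.exists():
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace")
    rows = []
    for meas in measurements:
        flags = ";".join(sorted(meas.trace.flags)) if meas.trace is not None else ""
        base = dict(
            molecule_id=meas.molecule_id,
            contour_nm=meas.contour_length_nm,
            contour_bp=meas.contour_length_bp,
            flags=flags,
        )
        if not meas.labels:
            rows.append(dict(base, label_index=pd.NA, arc_nm=np.nan, arc_bp=np.nan, prominence_nm=np.nan))
        for i, lab in enumerate(meas.labels):
            rows.append(
                dict(
                    base,
                    label_index=i,
                    arc_nm=lab.arc_pos_nm,
                    arc_bp=cal.nm_to_bp(lab.arc_pos_nm),
                    prominence_nm=lab.prominence_nm,
                )
            )
    table = pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return path


def read_measurements_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
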