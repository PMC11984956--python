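"""Reading and writing the package's on-disk formats.

Images travel as 16-bit multi-channel TIFF with pixel size and channel
names recorded in the ImageJ-style metadata (plus a JSON block in the
image description); localization tables as CSV with the header
``frame,x_nm,y_nm,z_nm,photons,crlb_xy_nm,channel``; measurement tables
as plain CSV with a JSON provenance sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .datatypes import ImageField, LOC_COLUMNS, validate_localizations


def write_image_field(path: str | Path, field: ImageField) -> None:
    """Write an :class:`ImageField` as 16-bit TIFF with metadata."""
    path = Path(path)
    data = np.asarray(field.data, dtype=float)
    data = np.clip(np.round(data), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    meta = {
        "pixel_size_nm": field.pixel_size_nm,
        "channel_names": list(field.channel_names),
    }
    px_um = field.pixel_size_nm / 1000.0
    tifffile.imwrite(
        path,
        data,
        imagej=True,
        resolution=(1.0 / px_um, 1.0 / px_um),
        metadata={"unit": "um", "axes": "CYX", "Info": json.dumps(meta)},
    )


def read_image_field(path: str | Path) -> ImageField:
    """Read a TIFF written by :func:`write_image_field`."""
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        info = None
        if tif.imagej_metadata:
            info = tif.imagej_metadata.get("Info")
    if data.ndim == 2:
        data = data[None]
    if info:
        meta = json.loads(info)
        return ImageField(
            data=data,
            pixel_size_nm=float(meta["pixel_size_nm"]),
            channel_names=tuple(meta["channel_names"]),
        )
    return ImageField(data=data, pixel_size_nm=1.0)


def write_localizations(path: str | Path, locs: pd.DataFrame) -> None:
    """Write a localization table as CSV in the standard dialect."""
    validate_localizations(locs)
    cols = LOC_COLUMNS + [c for c in locs.columns if c not in LOC_COLUMNS]
    locs[cols].to_csv(path, index=False)


def read_localizations(path: str | Path) -> pd.DataFrame:
    """Read a localization CSV and validate its schema."""
    locs = pd.read_csv(path)
    return validate_localizations(locs)


def write_provenance(path: str | Path, provenance: dict) -> None:
    """Write a JSON provenance block next to a measurement table."""

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating, np.bool_)):
            return o.item()
        return str(o)

    Path(path).write_text(json.dumps(provenance, indent=2, default=default))
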