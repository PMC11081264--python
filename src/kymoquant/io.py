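"""File IO: multi-frame TIFF movies, kymograph export, trace tables, config.

Calibration travels with the pixels: movies and kymographs are written as
grayscale TIFF with a JSON payload in the ImageDescription tag holding the
PixelGeometry, channel label, origin and orientation, so a read-back stack
is measurement-ready without side files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .core import Kymograph, Movie, PixelGeometry

__all__ = [
    "write_movie",
    "read_movie",
    "write_kymograph",
    "read_kymograph",
    "write_trace_table",
    "read_trace_table",
    "load_config",
    "dump_config",
]

TRACE_COLUMNS = ("trace_id", "channel", "t_s", "x_um")


def _geometry_meta(geometry: PixelGeometry, **extra) -> str:
    meta = {
        "pixel_size_um": geometry.pixel_size,
        "frame_interval_s": geometry.frame_interval,
        "n_frames": geometry.n_frames,
        "n_px": geometry.n_px,
        "line_width_px": geometry.line_width_px,
        **extra,
    }
    return json.dumps(meta)


def _parse_meta(desc: str | None) -> dict:
    if not desc:
        raise ValueError("TIFF lacks the calibration metadata this package writes")
    return json.loads(desc)


def write_movie(path: str | Path, movie: Movie) -> None:
    """Write a movie as a multi-frame grayscale float32 TIFF."""
    desc = _geometry_meta(
        movie.geometry,
        kind="movie",
        channel=movie.channel,
        origin=movie.origin,
        orientation=movie.orientation,
    )
    tifffile.imwrite(
        str(path), movie.data.astype(np.float32), description=desc, photometric="minisblack"
    )


def read_movie(path: str | Path) -> Movie:
    with tifffile.TiffFile(str(path)) as tif:
        data = tif.asarray().astype(float)
        meta = _parse_meta(tif.pages[0].description)
    if data.ndim == 2:  # single frame stored flat
        data = data[None, :, :]
    geom = PixelGeometry(
        pixel_size=meta["pixel_size_um"],
        frame_interval=meta["frame_interval_s"],
        n_frames=meta["n_frames"],
        n_px=meta["n_px"],
        line_width_px=meta["line_width_px"],
    )
    return Movie(
        data=data,
        geometry=geom,
        channel=meta.get("channel", "A"),
        origin=int(meta.get("origin", 0)),
        orientation=int(meta.get("orientation", 1)),
    )


def write_kymograph(path: str | Path, kymo: Kymograph) -> None:
    """Export a kymograph as TIFF (``.tif``) or delimited matrix (anything else)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        desc = _geometry_meta(
            kymo.geometry,
            kind="kymograph",
            channel=kymo.channel,
            origin=kymo.origin,
            orientation=kymo.orientation,
            time_offset_s=kymo.time_offset_s,
        )
        tifffile.imwrite(
            str(path), kymo.data.astype(np.float32), description=desc, photometric="minisblack"
        )
    else:
        np.savetxt(str(path), kymo.data, delimiter="\t")


def read_kymograph(path: str | Path) -> Kymograph:
    with tifffile.TiffFile(str(path)) as tif:
        data = tif.asarray().astype(float)
        meta = _parse_meta(tif.pages[0].description)
    geom = PixelGeometry(
        pixel_size=meta["pixel_size_um"],
        frame_interval=meta["frame_interval_s"],
        n_frames=meta["n_frames"],
        n_px=meta["n_px"],
        line_width_px=meta["line_width_px"],
    )
    return Kymograph(
        data=data,
        geometry=geom,
        channel=meta.get("channel", "A"),
        origin=int(meta.get("origin", 0)),
        orientation=int(meta.get("orientation", 1)),
        time_offset_s=float(meta.get("time_offset_s", 0.0)),
    )


def write_trace_table(path: str | Path, table: pd.DataFrame) -> None:
    missing = [c for c in TRACE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"trace table missing columns: {missing}")
    table.to_csv(path, index=False)


def read_trace_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def dump_config(path: str | Path, config: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
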