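"""File-format plumbing: TIFF frames, manifests, results CSV, configs.

Frames are written as 16-bit grayscale TIFF named
``{well}_t{####}h_{channel}.tif``.  Filenames are advisory: the
``manifest.csv`` written next to the images is the source of truth for
well/timepoint/channel/scale metadata.  Results are long-format CSV
(one row per well x timepoint x channel x metric) so they can be fed
directly to plotting and statistics.  Every run directory also gets a
``provenance.json`` with the seed, the package version and a hash of
the generating configuration.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .frames import Channel, ImageFrame

__all__ = [
    "frame_filename",
    "write_frame",
    "read_frame",
    "write_manifest",
    "load_manifest",
    "load_config",
    "dump_config",
    "write_provenance",
    "write_results",
]

MANIFEST_COLUMNS = [
    "path",
    "well_id",
    "t_h",
    "channel",
    "um_per_px",
    "defocus_z_um",
]


def frame_filename(frame: ImageFrame) -> str:
    return f"{frame.well_id or 'well'}_t{int(round(frame.t_h)):04d}h_{frame.channel.value}.tif"


def write_frame(frame: ImageFrame, directory: Path) -> dict:
    """Write one frame as 16-bit TIFF; returns its manifest row."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / frame_filename(frame)
    tifffile.imwrite(path, frame.pixels.astype(np.uint16))
    return {
        "path": path.name,
        "well_id": frame.well_id,
        "t_h": frame.t_h,
        "channel": frame.channel.value,
        "um_per_px": frame.um_per_px,
        "defocus_z_um": frame.defocus_z_um,
    }


def read_frame(row: pd.Series | dict, directory: Path) -> ImageFrame:
    """Read one frame back from a manifest row."""
    directory = Path(directory)
    pixels = tifffile.imread(directory / str(row["path"]))
    return ImageFrame(
        pixels=pixels,
        um_per_px=float(row["um_per_px"]),
        channel=Channel(row["channel"]),
        defocus_z_um=float(row["defocus_z_um"]),
        well_id=str(row["well_id"]),
        t_h=float(row["t_h"]),
    )


def write_manifest(rows: list[dict], directory: Path) -> Path:
    path = Path(directory) / "manifest.csv"
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, index=False)
    return path


def load_manifest(directory: Path) -> pd.DataFrame:
    path = Path(directory) / "manifest.csv"
    if not path.exists():
        raise FileNotFoundError(f"no manifest.csv in {directory}")
    return pd.read_csv(path)


def load_config(path: Path) -> dict:
    """Load a YAML or JSON configuration file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def dump_config(cfg: dict, path: Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(cfg, indent=2, sort_keys=True))
    else:
        path.write_text(yaml.safe_dump(cfg, sort_keys=True))


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def write_provenance(directory: Path, cfg: dict, seed: int | None) -> Path:
    from . import __version__

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / "provenance.json"
    path.write_text(
        json.dumps(
            {
                "seed": seed,
                "config_hash": config_hash(cfg),
                "version": __version__,
                "config": cfg,
            },
            indent=2,
            sort_keys=True,
            default=str,
        )
    )
    return path


def write_results(df: pd.DataFrame, path: Path, overwrite: bool = False) -> Path:
    """Write a long-format results CSV; refuses to overwrite by default."""
    path = Path(path)
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite/--force to replace it")
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path
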