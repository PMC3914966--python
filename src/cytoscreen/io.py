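"""File discovery and plate-map / table I/O.

Images follow the naming convention ``<plate>/<well>_f<field>_<channel>.tif``
with channel ∈ {dna, cell, mitotic}; an index CSV can override the
convention. All tabular artifacts are plain CSV.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import InputError
from .screen_stats import ROLES
from .segmentation import FieldImage

log = logging.getLogger(__name__)

PLATE_MAP_COLUMNS = [
    "plate_id",
    "well_id",
    "role",
    "compound_id",
    "dose_uM",
    "timepoint_h",
    "excluded",
]

_FIELD_RE = re.compile(r"^(?P<well>[A-H]\d{2})_f(?P<field>\d+)_(?P<channel>dna|cell|mitotic)\.tiff?$")


@dataclass(frozen=True)
class FieldFiles:
    """Paths of one field's three channel images."""

    plate_id: str
    well_id: str
    field_index: int
    paths: tuple[tuple[str, Path], ...]  # ((channel, path), ...) hashable

    @property
    def channel_paths(self) -> dict[str, Path]:
        return dict(self.paths)


def read_plate_map(path: str | Path) -> pd.DataFrame:
    """Read and validate a plate-map CSV into a layout table.

    Control rows may leave ``compound_id`` empty; duplicate wells, missing
    columns and unknown roles are rejected.
    """
    df = pd.read_csv(path, dtype={"plate_id": str, "well_id": str, "compound_id": str})
    missing = [c for c in PLATE_MAP_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"plate map {path}: missing columns {missing}")
    dup = df.duplicated(subset=["plate_id", "well_id"])
    if dup.any():
        dupes = df.loc[dup, ["plate_id", "well_id"]].to_records(index=False).tolist()
        raise InputError(f"plate map {path}: duplicate well rows {dupes}")
    bad = set(df["role"].unique()) - set(ROLES)
    if bad:
        raise InputError(f"plate map {path}: unknown roles {sorted(bad)}")
    df["compound_id"] = df["compound_id"].fillna("")
    df["excluded"] = df["excluded"].fillna(False).astype(bool)
    return df


def discover_fields(root_dir: str | Path, index_csv: str | Path | None = None) -> list[FieldFiles]:
    """Group channel TIFFs into per-field triplets.

    Incomplete triplets are logged and skipped; zero complete triplets is
    an error. ``index_csv`` (columns plate_id, well_id, field_index,
    channel, path) overrides the directory naming convention.
    """
    root = Path(root_dir)
    if not root.is_dir():
        raise InputError(f"image root {root} is not a directory")
    groups: dict[tuple[str, str, int], dict[str, Path]] = {}
    if index_csv is not None:
        idx = pd.read_csv(index_csv, dtype={"plate_id": str, "well_id": str})
        for _, r in idx.iterrows():
            key = (r["plate_id"], r["well_id"], int(r["field_index"]))
            groups.setdefault(key, {})[r["channel"]] = root / r["path"]
    else:
        for path in sorted(root.glob("*/*.tif")) + sorted(root.glob("*/*.tiff")):
            m = _FIELD_RE.match(path.name)
            if not m:
                log.warning("ignoring unrecognised file name %s", path)
                continue
            key = (path.parent.name, m["well"], int(m["field"]))
            groups.setdefault(key, {})[m["channel"]] = path

    out = []
    for (plate, well, fidx), chans in sorted(groups.items()):
        if set(chans) != {"dna", "cell", "mitotic"}:
            log.warning(
                "skipping %s/%s field %d: incomplete channel set %s",
                plate, well, fidx, sorted(chans),
            )
            continue
        out.append(
            FieldFiles(plate, well, fidx, tuple(sorted(chans.items())))
        )
    if not out:
        raise InputError(f"no complete (dna, cell, mitotic) field triplets under {root}")
    return out


def read_field(files: FieldFiles, pixel_size_um: float) -> FieldImage:
    """Load one field's three single-plane grayscale TIFFs."""
    channels = {}
    for channel, path in files.channel_paths.items():
        arr = tifffile.imread(path)
        if arr.ndim != 2:
            raise InputError(f"{path}: expected a single-plane grayscale image")
        channels[channel] = np.asarray(arr, dtype=float)
    return FieldImage(
        plate_id=files.plate_id,
        well_id=files.well_id,
        field_index=files.field_index,
        channels=channels,
        pixel_size_um=pixel_size_um,
    )


def write_field_tiffs(fieldimg: FieldImage, root_dir: str | Path) -> list[Path]:
    """Write a field's channels using the naming convention (16-bit)."""
    plate_dir = Path(root_dir) / fieldimg.plate_id
    plate_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for channel, arr in fieldimg.channels.items():
        path = plate_dir / f"{fieldimg.well_id}_f{fieldimg.field_index}_{channel}.tif"
        tifffile.imwrite(path, np.clip(arr, 0, 65535).astype(np.uint16))
        written.append(path)
    return written


def write_csv(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path
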