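"""File I/O: well addressing, plate maps, feature/score/hit tables, TIFF
fields with sidecar channel maps, and the YAML run configuration.

Conventions: wells are letter-row + zero-padded column ("A01".."P24"); CSVs
are comma-separated UTF-8 with a mandatory header and "." decimals; undefined
statistics serialise as empty fields, never 0 or a sentinel.
"""

from __future__ import annotations

import json
import string
from dataclasses import dataclass, field as dc_field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import tifffile
import yaml

from .imaging import ImageSet

__all__ = [
    "PlateMapError", "ConfigError", "well_name", "parse_well",
    "read_plate_map", "write_plate_map",
    "write_features", "read_features", "write_scores", "write_hits",
    "write_field_tiff", "read_field_tiff", "RunConfig",
]

ROLES = {"negative_control", "positive_control", "compound", "empty"}

_ROW_LETTERS = string.ascii_uppercase


class PlateMapError(ValueError):
    """Malformed plate map."""


class ConfigError(ValueError):
    """Malformed run configuration."""


def well_name(row: int, col: int) -> str:
    """0-based (row, col) -> 'A01'-style address."""
    if not (0 <= row < 26) or col < 0:
        raise ValueError(f"bad well indices ({row}, {col})")
    return f"{_ROW_LETTERS[row]}{col + 1:02d}"


def parse_well(name: str) -> tuple[int, int]:
    """'A01'-style address -> 0-based (row, col)."""
    name = str(name).strip()
    if len(name) < 2 or name[0].upper() not in _ROW_LETTERS or not name[1:].isdigit():
        raise ValueError(f"bad well address {name!r}")
    return _ROW_LETTERS.index(name[0].upper()), int(name[1:]) - 1


PLATE_MAP_COLUMNS = ["well", "row", "col", "role", "compound_id",
                     "concentration_uM", "cell_line"]


def read_plate_map(path) -> pd.DataFrame:
    """Read and validate a plate-map CSV.

    Requires columns well, role, compound_id, concentration_uM, cell_line
    (row/col are derived from the well address if absent). Roles must be in
    the fixed vocabulary and well addresses unique.
    """
    df = pd.read_csv(path, dtype={"well": str, "role": str})
    missing = {"well", "role"} - set(df.columns)
    if missing:
        raise PlateMapError(f"plate map missing columns {sorted(missing)}")
    dup = df["well"][df["well"].duplicated()].tolist()
    if dup:
        raise PlateMapError(f"duplicate well address(es): {sorted(set(dup))}")
    bad_roles = sorted(set(df["role"]) - ROLES)
    if bad_roles:
        raise PlateMapError(f"unknown role(s) {bad_roles}; allowed: {sorted(ROLES)}")
    rc = [parse_well(w) for w in df["well"]]  # raises on malformed addresses
    df["row"] = [r for r, _ in rc]
    df["col"] = [c for _, c in rc]
    if "concentration_uM" in df.columns:
        try:
            df["concentration_uM"] = pd.to_numeric(df["concentration_uM"])
        except (ValueError, TypeError) as e:
            raise PlateMapError(f"non-numeric concentration: {e}") from None
    for col in ("compound_id", "cell_line"):
        if col not in df.columns:
            df[col] = ""
        df[col] = df[col].fillna("")
    if "concentration_uM" not in df.columns:
        df["concentration_uM"] = np.nan
    return df[PLATE_MAP_COLUMNS]


def write_plate_map(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def write_features(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    df.to_csv(path, index=False)  # NaN -> empty field
    return path


def read_features(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"well": str, "role": str, "compound_id": str})
    if "qc_flags" in df.columns:
        df["qc_flags"] = df["qc_flags"].fillna("")
    return df


def write_scores(scores, path) -> Path:
    path = Path(path)
    scores.scores.to_csv(path, index=False)
    return path


def write_hits(hits: pd.DataFrame, path) -> Path:
    path = Path(path)
    hits.to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# image fields: one multi-page TIFF per field + a sidecar JSON channel map


def write_field_tiff(out_dir, img: ImageSet) -> Path:
    """Write `<well>_f<field>.tif` (one page per channel, float32) and a
    sidecar `<stem>.channels.json` recording channel order and pixel size."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    names = sorted(img.channels)
    stack = np.stack([np.asarray(img.channels[n], dtype=np.float32) for n in names])
    path = out_dir / f"{img.well}_f{img.field:02d}.tif"
    tifffile.imwrite(path, stack, photometric="minisblack")
    sidecar = {"channels": names, "pixel_size_um": img.pixel_size,
               "well": img.well, "field": img.field}
    path.with_suffix(".channels.json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_field_tiff(path) -> ImageSet:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".channels.json").read_text())
    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None]
    names = sidecar["channels"]
    if len(names) != stack.shape[0]:
        raise ValueError(f"{path}: sidecar lists {len(names)} channels, "
                         f"TIFF has {stack.shape[0]} pages")
    channels = {n: stack[i].astype(np.float64) for i, n in enumerate(names)}
    return ImageSet(channels=channels, pixel_size=float(sidecar["pixel_size_um"]),
                    well=sidecar.get("well", ""), field=int(sidecar.get("field", 0)))


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Validated pipeline configuration; round-trips losslessly via YAML."""

    mode: str = "features"  # features | images
    seed: int = 0
    out_dir: str = "ldscreen_run"
    n_compounds: int = 348
    fields_per_well: int = 12
    plate: dict = dc_field(default_factory=dict)  # make_default_plate overrides
    planted: dict = dc_field(default_factory=dict)  # compound_id -> profile kwargs
    scene: dict = dc_field(default_factory=dict)  # SceneSpec overrides
    noise: dict | None = None  # per-parameter well noise SDs
    segmentation: dict = dc_field(default_factory=dict)
    scoring: dict = dc_field(default_factory=dict)  # reference_source, robust_sd
    thresholds: dict = dc_field(default_factory=dict)
    directions: dict = dc_field(default_factory=dict)
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.mode not in ("features", "images"):
            raise ConfigError(f"mode must be 'features' or 'images', got {self.mode!r}")
        if not isinstance(self.seed, int):
            raise ConfigError("seed must be an integer")

    @classmethod
    def from_dict(cls, data: Mapping) -> "RunConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ConfigError("config must be a YAML mapping")
        return cls.from_dict(data)

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=True))
        return path
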