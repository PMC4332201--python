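"""File I/O: TIFF fields, manifests, cell tables and configuration.

All on-disk artifacts are plain formats: single-plane grayscale TIFF (8 or
16 bit) for images and label maps, CSV for tables, YAML for configuration
and JSON for reports.  A :class:`FieldManifest` row names one channel of
one field at one frame; the (field_id, frame, channel) triple is unique.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .core import (
    CHANNELS,
    ConfigurationError,
    ImageField,
    InvalidConfigError,
    MissingChannelError,
)
from .quantify import CellRecord, ChannelStats

__all__ = [
    "FieldManifest",
    "read_field",
    "write_field",
    "write_simulation",
    "records_to_frame",
    "records_from_frame",
    "load_config",
    "save_config",
    "write_json",
]

MANIFEST_COLUMNS = (
    "field_id",
    "condition",
    "treatment",
    "time_h",
    "frame",
    "channel",
    "file_path",
    "pixel_size_um",
)

#: vendor/filter channel names mapped onto the canonical four
CHANNEL_ALIASES = {
    "dapi": "hoechst",
    "hoechst": "hoechst",
    "cy2": "anion",
    "fba": "anion",
    "anion": "anion",
    "cy3": "lysotracker",
    "lysotracker": "lysotracker",
    "marker": "lysotracker",
    "cy5": "pi",
    "pi": "pi",
    "propidium_iodide": "pi",
}


class FieldManifest:
    """Table of image files making up the fields of one run."""

    def __init__(self, frame: pd.DataFrame):
        missing = set(MANIFEST_COLUMNS) - set(frame.columns)
        if missing:
            raise InvalidConfigError(f"manifest lacks columns {sorted(missing)}")
        frame = frame.copy()
        frame["channel"] = (
            frame["channel"].astype(str).str.lower().map(CHANNEL_ALIASES)
        )
        if frame["channel"].isna().any():
            raise InvalidConfigError("manifest contains unknown channel names")
        key = frame[["field_id", "frame", "channel"]]
        if key.duplicated().any():
            raise InvalidConfigError("(field_id, frame, channel) must be unique")
        self.frame = frame

    @classmethod
    def from_csv(cls, path: str | Path) -> "FieldManifest":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)

    def field_ids(self) -> list[str]:
        return list(dict.fromkeys(self.frame["field_id"]))

    def frames_of(self, field_id: str) -> list[int]:
        sub = self.frame[self.frame["field_id"] == field_id]
        return sorted(sub["frame"].unique())

    def rows_for(self, field_id: str, frame: int) -> pd.DataFrame:
        sub = self.frame
        return sub[(sub["field_id"] == field_id) & (sub["frame"] == frame)]


def _load_plane(path: str | Path) -> np.ndarray:
    try:
        arr = tifffile.imread(path)
    except (FileNotFoundError, OSError, ValueError) as exc:
        raise ConfigurationError(f"cannot read image file {path!r}: {exc}") from exc
    if arr.ndim != 2:
        raise ConfigurationError(f"{path!r} is not a single-plane grayscale image")
    if arr.dtype == np.uint8 or arr.dtype == np.uint16:
        return arr.astype(np.uint16)
    if np.issubdtype(arr.dtype, np.integer):
        return arr.astype(np.uint16)
    raise ConfigurationError(f"{path!r}: unsupported dtype {arr.dtype}")


def read_field(
    manifest: FieldManifest,
    field_id: str,
    frame: int = 1,
    required_channels: Sequence[str] = CHANNELS,
) -> ImageField:
    """Load one field/frame from disk into a common uint16 representation.

    Rows with an empty ``file_path`` mark a channel as explicitly absent;
    a required channel that is absent or unlisted raises.  All present
    channels must agree in dimensions.
    """
    rows = manifest.rows_for(field_id, frame)
    if rows.empty:
        raise ConfigurationError(f"no manifest rows for {field_id!r} frame {frame}")
    channels: dict[str, np.ndarray] = {}
    for _, row in rows.iterrows():
        path = row["file_path"]
        if pd.isna(path) or str(path) == "":
            continue  # explicitly absent
        channels[row["channel"]] = _load_plane(path)
    for ch in required_channels:
        if ch not in channels:
            raise MissingChannelError(
                f"required channel {ch!r} absent for field {field_id!r}"
            )
    shapes = {a.shape for a in channels.values()}
    if len(shapes) > 1:
        raise ConfigurationError(f"channel dimensions differ for {field_id!r}: {shapes}")
    meta = rows.iloc[0]
    return ImageField(
        channels=channels,
        pixel_size_um=float(meta["pixel_size_um"]),
        field_id=field_id,
        condition=str(meta["condition"]),
        treatment=str(meta["treatment"]),
        time_h=float(meta["time_h"]),
        frame=int(frame),
    )


def write_field(field: ImageField, outdir: str | Path) -> pd.DataFrame:
    """Write each channel as ``{field}_{channel}_{frame}.tif``; return
    the manifest rows describing the files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for ch in CHANNELS:
        if not field.has_channel(ch):
            continue
        name = f"{field.field_id}_{ch}_{field.frame:04d}.tif"
        tifffile.imwrite(outdir / name, field.channel(ch).astype(np.uint16))
        rows.append(
            {
                "field_id": field.field_id,
                "condition": field.condition,
                "treatment": field.treatment,
                "time_h": field.time_h,
                "frame": field.frame,
                "channel": ch,
                "file_path": str(outdir / name),
                "pixel_size_um": field.pixel_size_um,
            }
        )
    return pd.DataFrame(rows)


def write_simulation(
    fields: Sequence[ImageField], truth: pd.DataFrame, outdir: str | Path
) -> FieldManifest:
    """Write a simulated field sequence: TIFFs + ground_truth.csv +
    manifest.csv.  Returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = pd.concat([write_field(f, outdir) for f in fields], ignore_index=True)
    manifest = FieldManifest(rows)
    manifest.to_csv(outdir / "manifest.csv")
    truth.to_csv(outdir / "ground_truth.csv", index=False)
    return manifest


# ---------------------------------------------------------------------------
# cell-record tables

_STAT_FIELDS = ("mean", "sd", "integrated", "pixel_count")


def records_to_frame(records: Sequence[CellRecord]) -> pd.DataFrame:
    """Flatten records into a tidy wide table (one row per cell)."""
    rows = []
    for rec in records:
        row: dict = {
            "field_id": rec.field_id,
            "label": rec.label,
            "centroid_x_px": rec.centroid_x_px,
            "centroid_y_px": rec.centroid_y_px,
            "area_um2": rec.area_um2,
            "max_feret_um": rec.max_feret_um,
            "circularity": rec.circularity,
            "fba_over_hoechst": rec.fba_over_hoechst,
            "viable": rec.viable,
            "flags": ";".join(sorted(rec.flags)),
            "retained": rec.retained,
        }
        for (ch, roi), st in sorted(rec.stats.items()):
            for f in _STAT_FIELDS:
                row[f"{ch}_{roi}_{f}"] = getattr(st, f)
        for (ch, roi), v in sorted(rec.corrected.items()):
            row[f"{ch}_{roi}_corrected"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def records_from_frame(frame: pd.DataFrame) -> list[CellRecord]:
    """Inverse of :func:`records_to_frame`."""
    records = []
    stat_cols = [c for c in frame.columns if c.endswith("_mean")]
    keys = [tuple(c.rsplit("_", 1)[0].rsplit("_", 1)) for c in stat_cols]
    for _, row in frame.iterrows():
        rec = CellRecord(
            label=int(row["label"]),
            field_id=str(row.get("field_id", "")),
            area_um2=float(row.get("area_um2", np.nan)),
            max_feret_um=float(row.get("max_feret_um", np.nan)),
            circularity=float(row.get("circularity", np.nan)),
            centroid_x_px=float(row.get("centroid_x_px", np.nan)),
            centroid_y_px=float(row.get("centroid_y_px", np.nan)),
        )
        fb = row.get("fba_over_hoechst")
        rec.fba_over_hoechst = None if pd.isna(fb) else float(fb)
        flags = row.get("flags", "")
        if isinstance(flags, str) and flags:
            rec.flags = set(flags.split(";"))
        v = row.get("viable")
        rec.viable = None if pd.isna(v) else bool(v)
        for ch, roi in keys:
            base = f"{ch}_{roi}"
            if pd.isna(row[f"{base}_mean"]):
                continue
            rec.stats[(ch, roi)] = ChannelStats(
                mean=float(row[f"{base}_mean"]),
                sd=float(row[f"{base}_sd"]),
                integrated=float(row[f"{base}_integrated"]),
                pixel_count=int(row[f"{base}_pixel_count"]),
            )
            corr = row.get(f"{base}_corrected")
            if corr is not None and not pd.isna(corr):
                rec.corrected[(ch, roi)] = float(corr)
        records.append(rec)
    return records


# ---------------------------------------------------------------------------
# config / report helpers


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigurationError(f"config {path!r} did not parse to a mapping")
    return cfg


def save_config(config: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if hasattr(obj, "__dataclass_fields__"):
        return asdict(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def write_json(payload: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
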