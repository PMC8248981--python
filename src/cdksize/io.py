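"""Table, image and trace I/O.

CellRecord tables round-trip through CSV and Parquet under a fixed schema
(nullable activity, boolean flags preserved).  Images are multi-page TIFFs
in the documented channel order BF1, BF2, biosensor, level, with the pixel
size carried in the JSON image description.  Lineage traces are long-format
CSV plus a JSON events sidecar.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import SchemaError
from .lineage import LineageEvent, LineageTrace
from .quantify import CellImage

log = logging.getLogger(__name__)

__all__ = [
    "RECORD_SCHEMA",
    "CHANNEL_ORDER",
    "read_records",
    "write_records",
    "write_image",
    "read_image",
    "read_images",
    "write_traces",
    "read_traces",
]

#: CellRecord column dtypes; activity is nullable (quantification can fail
#: per-cell), gated/pp2a are pandas booleans.
RECORD_SCHEMA: dict[str, str] = {
    "cell_id": "string",
    "sample_id": "string",
    "time_s": "float64",
    "genotype": "string",
    "pp2a": "boolean",
    "ploidy": "Int64",
    "length_um": "float64",
    "radius_um": "float64",
    "area_px2": "float64",
    "volume_fl": "float64",
    "cdk_level_au": "float64",
    "activity_nc": "Float64",
    "focus_grad_rms": "float64",
    "gated": "boolean",
}

CHANNEL_ORDER = ("bf1", "bf2", "biosensor", "level")


def _apply_schema(df: pd.DataFrame) -> pd.DataFrame:
    out = pd.DataFrame(index=df.index)
    for col, dtype in RECORD_SCHEMA.items():
        if col not in df.columns:
            raise SchemaError(f"missing column {col!r}")
        try:
            out[col] = df[col].astype(dtype)
        except (TypeError, ValueError) as exc:
            raise SchemaError(f"column {col!r} cannot be cast to {dtype}: {exc}") from exc
    extra = [c for c in df.columns if c not in RECORD_SCHEMA]
    for col in extra:
        out[col] = df[col]
    return out


def write_records(records: pd.DataFrame, path: str | Path) -> Path:
    """Write a CellRecord table; dialect chosen by suffix (.csv/.parquet)."""
    path = Path(path)
    df = _apply_schema(records)
    if path.suffix == ".csv":
        df.to_csv(path, index=False)
    elif path.suffix == ".parquet":
        df.to_parquet(path, index=False)
    else:
        raise ValueError(f"unsupported table format {path.suffix!r}")
    return path


def read_records(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix == ".csv":
        df = pd.read_csv(path)
        if len(df) == 0:
            df = pd.DataFrame({c: pd.Series(dtype=t) for c, t in RECORD_SCHEMA.items()})
    elif path.suffix == ".parquet":
        df = pd.read_parquet(path)
    else:
        raise ValueError(f"unsupported table format {path.suffix!r}")
    return _apply_schema(df)


def write_image(image: CellImage, path: str | Path) -> Path:
    """Multi-page TIFF in the documented channel order with metadata."""
    path = Path(path)
    stack = np.stack(
        [
            np.asarray(image.bf1, dtype=np.float32),
            np.asarray(image.bf2, dtype=np.float32),
        ]
        + [np.asarray(image.channels[c], dtype=np.float32) for c in CHANNEL_ORDER[2:]]
    )
    meta = {
        "pixel_size_um": image.pixel_size_um,
        "channels": list(CHANNEL_ORDER),
        "cell_id": image.cell_id,
    }
    tifffile.imwrite(path, stack, metadata=meta, photometric="minisblack")
    return path


def read_image(path: str | Path, pixel_size_um: float | None = None) -> CellImage:
    """Read one multi-page TIFF back into a :class:`CellImage`.

    Pixel size from the file's metadata takes precedence over the
    ``pixel_size_um`` fallback.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        stack = tif.asarray()
        meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
    channels = list(meta.get("channels", CHANNEL_ORDER))
    if stack.ndim != 3 or stack.shape[0] != len(channels):
        raise ValueError(
            f"{path.name}: expected {len(channels)} channel pages, got shape {stack.shape}"
        )
    px = meta.get("pixel_size_um", pixel_size_um)
    if px is None:
        raise ValueError(f"{path.name}: no pixel size in metadata and no fallback given")
    named = dict(zip(channels, stack))
    missing = [c for c in CHANNEL_ORDER if c not in named]
    if missing:
        raise ValueError(f"{path.name}: missing channels {missing}")
    return CellImage(
        bf1=named["bf1"],
        bf2=named["bf2"],
        channels={c: named[c] for c in channels if c not in ("bf1", "bf2")},
        pixel_size_um=float(px),
        cell_id=meta.get("cell_id") or path.stem,
    )


def read_images(path_or_dir: str | Path, pixel_size_um: float | None = None):
    """Lazily yield CellImages from a TIFF file or a directory of TIFFs.

    Per-file errors (wrong channel count, missing metadata) are logged and
    the stream continues.
    """
    p = Path(path_or_dir)
    files = sorted(p.glob("*.tif*")) if p.is_dir() else [p]
    for f in files:
        try:
            yield read_image(f, pixel_size_um=pixel_size_um)
        except Exception as exc:  # per-file failure must not kill the stream
            log.error("skipping %s: %s", f, exc)


def write_traces(traces: list[LineageTrace], csv_path: str | Path) -> tuple[Path, Path]:
    """Long-format CSV (cell_id, frame, time_min, size, level, activity)
    plus a ``<stem>.events.json`` sidecar."""
    csv_path = Path(csv_path)
    frames = []
    sidecar = {"frame_interval_min": None, "events": {}}
    for tr in traces:
        df = tr.frames.copy()
        df.insert(0, "frame", np.arange(len(df)))
        df.insert(0, "cell_id", tr.cell_id)
        frames.append(df)
        sidecar["events"][tr.cell_id] = [[e.frame, e.kind] for e in tr.events]
        sidecar["frame_interval_min"] = tr.frame_interval_min
    pd.concat(frames, ignore_index=True).to_csv(csv_path, index=False)
    events_path = csv_path.with_suffix(".events.json")
    events_path.write_text(json.dumps(sidecar, indent=1))
    return csv_path, events_path


def read_traces(csv_path: str | Path) -> list[LineageTrace]:
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    events_path = csv_path.with_suffix(".events.json")
    sidecar = json.loads(events_path.read_text()) if events_path.exists() else {}
    interval = sidecar.get("frame_interval_min")
    ev_map = sidecar.get("events", {})
    traces = []
    for cell_id, grp in df.groupby("cell_id", sort=False):
        frames = grp.drop(columns=["cell_id", "frame"]).reset_index(drop=True)
        dt = interval
        if dt is None:
            t = frames["time_min"].to_numpy()
            dt = float(t[1] - t[0]) if len(t) > 1 else 1.0
        traces.append(
            LineageTrace(
                cell_id=str(cell_id),
                frames=frames,
                frame_interval_min=float(dt),
                events=[LineageEvent(int(f), str(k)) for f, k in ev_map.get(str(cell_id), [])],
            )
        )
    return traces
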