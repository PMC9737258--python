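"""Readers and writers: OME-TIFF images, CSV tables, JSON reports.

CSV files may start with ``# key=value`` provenance lines (software version,
seed, config hash); readers skip them.  Schema violations are reported with
row and column coordinates.
"""

from __future__ import annotations

import datetime
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .zonation import MultichannelStack

__all__ = [
    "ConfigError",
    "DataError",
    "read_image",
    "write_image",
    "read_table",
    "write_table",
    "write_report",
    "provenance_meta",
    "config_hash",
]


class ConfigError(Exception):
    """Invalid or missing configuration (CLI exit code 2)."""

    exit_code = 2


class DataError(Exception):
    """Malformed or missing input data (CLI exit code 3)."""

    exit_code = 3


def config_hash(config_obj) -> str:
    """Stable sha256 of a JSON-serialisable configuration object."""
    blob = json.dumps(config_obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def provenance_meta(seed=None, cfg_hash=None, timestamp: bool = True) -> dict:
    meta = {"hma_version": __version__}
    if seed is not None:
        meta["seed"] = seed
    if cfg_hash is not None:
        meta["config_sha256"] = cfg_hash
    if timestamp:
        meta["written"] = datetime.datetime.now(datetime.timezone.utc).isoformat()
    return meta


def write_image(stack: MultichannelStack, path) -> None:
    """Write a multichannel stack as OME-TIFF with named channels."""
    path = Path(path)
    metadata = {
        "axes": "CZYX",
        "Channel": {"Name": list(stack.channel_names)},
        "PhysicalSizeX": stack.um_per_px,
        "PhysicalSizeXUnit": "µm",
        "PhysicalSizeY": stack.um_per_px,
        "PhysicalSizeYUnit": "µm",
    }
    if stack.z_step_um is not None:
        metadata["PhysicalSizeZ"] = stack.z_step_um
        metadata["PhysicalSizeZUnit"] = "µm"
    tifffile.imwrite(path, stack.pixels, ome=True, metadata=metadata)


def _ome_channel_names(tf: tifffile.TiffFile) -> list[str] | None:
    if not tf.ome_metadata:
        return None
    try:
        meta = tifffile.xml2dict(tf.ome_metadata)
        image = meta["OME"]["Image"]
        if isinstance(image, list):
            image = image[0]
        chans = image["Pixels"]["Channel"]
        if isinstance(chans, dict):
            chans = [chans]
        names = [c.get("Name") for c in chans]
        if any(n is None for n in names):
            return None
        return [str(n) for n in names]
    except (KeyError, TypeError):
        return None


def _ome_pixel_size(tf: tifffile.TiffFile) -> float | None:
    if not tf.ome_metadata:
        return None
    try:
        meta = tifffile.xml2dict(tf.ome_metadata)
        image = meta["OME"]["Image"]
        if isinstance(image, list):
            image = image[0]
        return float(image["Pixels"]["PhysicalSizeX"])
    except (KeyError, TypeError, ValueError):
        return None


def read_image(path, channels: list[str] | None = None, um_per_px: float | None = None) -> MultichannelStack:
    """Read a (multichannel, multi-z) TIFF/OME-TIFF into a MultichannelStack.

    Channel names come from OME metadata; for plain TIFFs they must be
    supplied via ``channels``.  Likewise the pixel size comes from OME
    ``PhysicalSizeX`` unless ``um_per_px`` is given (an explicit argument
    always wins).
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"image file not found: {path}")
    with tifffile.TiffFile(path) as tf:
        series = tf.series[0]
        data = np.asarray(series.asarray())
        axes = series.axes
        names = _ome_channel_names(tf)
        scale = _ome_pixel_size(tf)

    # Normalise axis order to CZYX, inserting singleton axes where absent.
    axes = axes.replace("S", "C").replace("Q", "Z")
    if set(axes) - set("CZYX"):
        raise DataError(f"{path}: unsupported image axes {axes!r}")
    for needed in "CZYX":
        if needed not in axes:
            data = data[np.newaxis]
            axes = needed + axes
    data = np.moveaxis(data, [axes.index(a) for a in "CZYX"], [0, 1, 2, 3])

    if channels is not None:
        names = list(channels)
    if names is None:
        raise DataError(
            f"{path}: OME metadata carries no channel names; pass --channels "
            "(e.g. --channels red,green,blue)"
        )
    if len(names) != data.shape[0]:
        raise DataError(
            f"{path}: {len(names)} channel names for {data.shape[0]} channels"
        )
    if um_per_px is not None:
        scale = float(um_per_px)
    if scale is None:
        raise DataError(
            f"{path}: no pixel size in metadata; pass --scale-um-per-px"
        )
    return MultichannelStack(pixels=data, channel_names=names, um_per_px=scale)


def write_table(df: pd.DataFrame, path, meta: dict | None = None) -> None:
    """Write a CSV with optional ``# key=value`` provenance header lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for key, value in (meta or {}).items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, index=False)


def read_table(path, columns: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a CSV table, validating required columns and dtypes.

    ``columns`` maps required column names to 'number', 'int', 'bool' or
    'str'.  Violations raise :class:`DataError` naming the row (1-based,
    counting the header as row 1, ignoring comment lines) and column.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"table file not found: {path}")
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.ParserError as exc:
        raise DataError(f"{path}: malformed CSV: {exc}") from exc
    if columns:
        missing = [c for c in columns if c not in df.columns]
        if missing:
            raise DataError(f"{path}: missing columns {missing}")
        for col, kind in columns.items():
            if kind in ("number", "int"):
                coerced = pd.to_numeric(df[col], errors="coerce")
                bad = coerced.isna() & df[col].notna()
                if bad.any():
                    row = int(bad.idxmax()) + 2  # +1 header, +1 1-based
                    raise DataError(
                        f"{path}: row {row}, column {col!r}: not a number "
                        f"({df[col][bad.idxmax()]!r})"
                    )
                df[col] = coerced.astype(int) if kind == "int" else coerced
            elif kind == "bool":
                vals = pd.to_numeric(df[col], errors="coerce")
                bad = ~vals.isin([0, 1])
                if bad.any():
                    row = int(bad.idxmax()) + 2
                    raise DataError(
                        f"{path}: row {row}, column {col!r}: expected 0/1"
                    )
                df[col] = vals.astype(bool)
            else:
                df[col] = df[col].astype(str)
    return df


def write_report(obj: dict, path, schema_version: str = "1") -> None:
    """Write a JSON report with a schema version marker."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {"schema_version": schema_version, **obj}
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=False, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")
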