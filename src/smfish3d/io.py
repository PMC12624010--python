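"""File I/O: TIFF stacks with voxel-size sidecars, label masks, and
versioned CSV spot/cell tables.

Stacks are multi-page TIFF with plane order z-ascending; physical voxel
size travels in a JSON sidecar (``<name>.meta.json``) or OME metadata, with
a CLI override.  Tables are plain CSV with a schema-version header comment
so mismatched pipeline stages fail loudly instead of silently.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .detect import ImageStack

log = logging.getLogger("smfish3d")

SPOT_SCHEMA = "smfish3d-spot-table-v1"
CELL_SCHEMA = "smfish3d-cell-table-v1"


class FormatError(ValueError):
    """Unsupported or malformed input file."""


class SchemaError(ValueError):
    """Table schema version does not match this pipeline version."""


# ---------------------------------------------------------------------------
# stacks
# ---------------------------------------------------------------------------

def write_stack(stack: ImageStack, path: str | Path,
                field_id: str | None = None) -> None:
    """Write a stack as multi-page TIFF (z-ascending) plus a JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = stack.voxels
    if np.issubdtype(data.dtype, np.floating):
        data = np.round(np.clip(data, 0, 2 ** 16 - 1)).astype(np.uint16)
    tifffile.imwrite(str(path), data, photometric="minisblack")
    meta = {
        "voxel_size_nm": list(stack.voxel_size_nm),
        "channel_name": stack.channel_name,
        "plane_order": "z-ascending",
    }
    if field_id is not None:
        meta["field_id"] = field_id
    with open(path.with_suffix(path.suffix + ".meta.json"), "w") as fh:
        json.dump(meta, fh, indent=1)


def read_stack(path: str | Path,
               voxel_size_nm: tuple[float, float, float] | None = None,
               channel_name: str | None = None) -> ImageStack:
    """Read a multi-page TIFF stack; voxel size from sidecar, OME metadata,
    or the explicit override (in that order of preference for metadata,
    with the override winning when given)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(str(path)) as tf:
        arr = tf.asarray()
        ome_vs = _ome_voxel_size(tf)
    if arr.ndim == 3 and arr.shape[-1] in (3, 4) and arr.shape[0] > 8:
        # heuristically an RGB(A) image rather than a short z-stack
        raise FormatError(f"{path}: RGB TIFF is not a supported smFISH stack")
    if arr.ndim != 3:
        raise FormatError(
            f"{path}: expected a 3D z-stack, got {arr.ndim}D data")
    meta = _read_sidecar(path)
    vs = voxel_size_nm or meta.get("voxel_size_nm") or ome_vs
    if vs is None:
        raise FormatError(
            f"{path}: no voxel size in sidecar or OME metadata; "
            "pass an explicit voxel-size override")
    name = channel_name or meta.get("channel_name", "")
    return ImageStack(np.asarray(arr), tuple(float(v) for v in vs), name)


def _read_sidecar(path: Path) -> dict:
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    if sidecar.exists():
        with open(sidecar) as fh:
            return json.load(fh)
    return {}


def _ome_voxel_size(tf) -> tuple[float, float, float] | None:
    try:
        if not tf.is_ome:
            return None
        import xml.etree.ElementTree as ET

        root = ET.fromstring(tf.ome_metadata)
        ns = {"ome": root.tag.split("}")[0].strip("{")}
        px = root.find(".//ome:Pixels", ns)
        if px is None:
            return None
        unit_scale = {"nm": 1.0, "µm": 1000.0, "um": 1000.0}

        def get(axis):
            v = px.get(f"PhysicalSize{axis}")
            u = px.get(f"PhysicalSize{axis}Unit", "µm")
            return float(v) * unit_scale.get(u, 1000.0) if v else None

        z, y, x = get("Z"), get("Y"), get("X")
        if None in (z, y, x):
            return None
        return (z, y, x)
    except Exception:
        return None


def read_field_id(path: str | Path) -> str | None:
    return _read_sidecar(Path(path)).get("field_id")


# ---------------------------------------------------------------------------
# label masks
# ---------------------------------------------------------------------------

def write_mask(labels: np.ndarray, path: str | Path,
               field_id: str | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(str(path), labels.astype(np.int32))
    if field_id is not None:
        with open(path.with_suffix(path.suffix + ".meta.json"), "w") as fh:
            json.dump({"field_id": field_id}, fh)


# ---------------------------------------------------------------------------
# versioned CSV tables
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path: str | Path, schema: str,
                field_id: str | None = None) -> None:
    """Write a CSV with a ``# schema=...`` header comment for provenance."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# schema={schema}\n")
        if field_id is not None:
            fh.write(f"# field_id={field_id}\n")
        df.to_csv(fh, index=False)


def read_table(path: str | Path, expected_schema: str) -> pd.DataFrame:
    """Read a versioned CSV, checking the schema header."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    header = {}
    n_comments = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_comments += 1
            key, _, value = line.lstrip("# ").rstrip("\n").partition("=")
            header[key] = value
    found = header.get("schema")
    if found != expected_schema:
        raise SchemaError(
            f"{path}: schema {found!r} does not match expected "
            f"{expected_schema!r}")
    df = pd.read_csv(path, skiprows=n_comments)
    df.attrs["field_id"] = header.get("field_id")
    return df
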