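"""Reading and writing the toolkit's on-disk formats.

Stacks are multi-page grayscale TIFF (8/16-bit); masks are TIFF stacks of
0/1 planes; tables are plain CSV.  The qPCR well schema is
``plate,well,sample,gene,treatment,replicate,ct`` with an empty ct field as
the no-amplification sentinel; dilution series are ``gene,known_copies,ct``;
titer comparisons are ``condition,value``.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import SchemaError
from .image_titer import ImageStack, PunctaResult, RoiMaskSet


def read_stack(path, z_step_um: float = 1.5, pixel_size_um: float | None = None,
               channel: str = "DNA") -> ImageStack:
    vox = tifffile.imread(path)
    if vox.ndim == 2:
        vox = vox[None]
    return ImageStack(vox.astype(float), z_step_um=z_step_um,
                      pixel_size_um=pixel_size_um, channel=channel)


def write_stack(path, stack: ImageStack) -> None:
    """Write a stack as 16-bit multi-page TIFF (intensities clipped/rounded)."""
    data = np.clip(np.round(stack.voxels), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, data)


def read_masks(path) -> RoiMaskSet:
    m = tifffile.imread(path)
    return RoiMaskSet((np.asarray(m) > 0).astype(np.uint8))


def write_ground_truth(path, truth) -> None:
    """Ground truth of a synthetic stack as documented JSON."""
    payload = dataclasses.asdict(truth)
    payload["echo_planes"] = {str(k): v for k, v in payload["echo_planes"].items()}
    Path(path).write_text(json.dumps(payload, indent=2))


def puncta_result_to_json(result: PunctaResult) -> str:
    payload = dataclasses.asdict(result)
    if payload.get("planes_used") is not None:
        payload["planes_used"] = list(payload["planes_used"])
    return json.dumps(payload, indent=2)


def write_per_plane_csv(path, result: PunctaResult) -> None:
    if result.per_plane_counts is None or result.planes_used is None:
        raise ValueError("result carries no per-plane counts")
    z0 = result.planes_used[0]
    df = pd.DataFrame(
        {
            "plane_index": range(z0, z0 + len(result.per_plane_counts)),
            "count": result.per_plane_counts,
        }
    )
    df.to_csv(path, index=False)


def read_wells(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"plate", "well", "sample", "gene", "replicate", "ct"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"well CSV missing columns {sorted(missing)}")
    if "treatment" not in df.columns:
        df["treatment"] = ""
    df["treatment"] = df["treatment"].fillna("")
    return df


def write_wells(path, wells: pd.DataFrame) -> None:
    wells.to_csv(path, index=False)  # NaN ct -> empty field (sentinel)


def read_dilution(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"gene", "known_copies", "ct"} - set(df.columns)
    if missing:
        raise SchemaError(f"dilution CSV missing columns {sorted(missing)}")
    return df


def read_titer_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"condition", "value"} - set(df.columns)
    if missing:
        raise SchemaError(f"titer CSV missing columns {sorted(missing)}")
    return df


def read_ovariole_records(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "condition" not in df.columns:
        raise SchemaError("ovariole CSV missing 'condition' column")
    return df
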