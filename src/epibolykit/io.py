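"""Readers and writers for stacks, tables and configuration.

Stacks are multi-page TIFF files with a JSON sidecar (``<name>.json``
next to the TIFF) carrying voxel spacing and origin in µm — spacing is
never assumed isotropic and a missing sidecar is an error.  Tables are
tab-separated text with schema validation; unknown columns are
preserved and numeric formatting is locale-independent.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .records import ImageStack

SIDECAR_SUFFIX = ".json"


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write a stack as multi-page TIFF plus JSON spacing sidecar."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(stack.data), photometric="minisblack")
    sidecar = {
        "spacing_um_zyx": list(stack.spacing),
        "origin_um_zyx": list(stack.origin),
        "axes": "ZYX",
    }
    path.with_suffix(path.suffix + SIDECAR_SUFFIX).write_text(
        json.dumps(sidecar, indent=2)
    )


def read_stack(path: str | Path) -> ImageStack:
    """Read a multi-page TIFF stack; requires the JSON spacing sidecar."""
    path = Path(path)
    sidecar_path = path.with_suffix(path.suffix + SIDECAR_SUFFIX)
    if not sidecar_path.exists():
        raise FileNotFoundError(
            f"missing sidecar {sidecar_path.name}: voxel spacing metadata "
            "(spacing_um_zyx) is required; refusing to assume isotropy"
        )
    meta = json.loads(sidecar_path.read_text())
    if "spacing_um_zyx" not in meta:
        raise ValueError(f"sidecar {sidecar_path.name} lacks 'spacing_um_zyx'")
    data = tifffile.imread(path)
    return ImageStack(
        data=data,
        spacing=tuple(meta["spacing_um_zyx"]),
        origin=tuple(meta.get("origin_um_zyx", (0.0, 0.0, 0.0))),
    )


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a table as TSV (period decimal separator, no index)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def read_table(
    path: str | Path, required: list[str] | None = None
) -> pd.DataFrame:
    """Read a TSV table, validating required columns if given."""
    df = pd.read_csv(path, sep="\t")
    if required:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"table {Path(path).name} missing columns: {missing}")
    return df


def read_config(path: str | Path) -> dict:
    """Read a YAML or JSON configuration file into a dict."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text) or {}
    return json.loads(text)


def write_config(config: dict, path: str | Path) -> None:
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(config, sort_keys=False))
    else:
        path.write_text(json.dumps(config, indent=2))
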