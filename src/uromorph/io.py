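"""File-format helpers: RGB fields, 16-bit label masks, tables, configs."""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "read_image",
    "read_mask",
    "read_table",
    "read_yaml",
    "write_image",
    "write_mask",
    "write_table",
    "write_yaml",
]


def write_image(path: str | Path, rgb: np.ndarray) -> None:
    """Write an 8-bit RGB field as PNG or TIFF (by extension)."""
    iio.imwrite(Path(path), np.asarray(rgb, dtype=np.uint8))


def read_image(path: str | Path) -> np.ndarray:
    arr = iio.imread(Path(path))
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[..., :3]
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"{path}: expected an RGB image, got shape {arr.shape}")
    return arr.astype(np.uint8)


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    """Write a label mask as 16-bit single-channel PNG."""
    mask = np.asarray(mask)
    if mask.max() > np.iinfo(np.uint16).max:
        raise ValueError("more than 65535 labels cannot be stored as 16-bit PNG")
    iio.imwrite(Path(path), mask.astype(np.uint16))


def read_mask(path: str | Path) -> np.ndarray:
    return iio.imread(Path(path)).astype(np.int32)


def write_table(path: str | Path, df: pd.DataFrame, index: bool = False) -> None:
    df.to_csv(Path(path), index=index)


def read_table(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(Path(path), **kwargs)


def write_yaml(path: str | Path, data: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def read_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
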