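"""File I/O for images, masks and tables.

Images are single-channel TIFF (float32 in [0, 1]) with PNG previews;
masks are 8-bit TIFF with values {0, 255}; tables are CSV with declared
headers. Integer images are rescaled to [0, 1] by their dtype maximum
on read.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile


def read_image(path: str | Path, channel: int | None = None) -> np.ndarray:
    """Read a TIFF/PNG image as float32 in [0, 1].

    Integer dtypes are rescaled by their dtype maximum; float images
    are assumed to already be on [0, 1]. Multi-channel input requires
    an explicit ``channel``.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    if arr.ndim == 3:
        if channel is None:
            raise ValueError(
                f"{path.name} has {arr.shape[-1]} channels; pass channel="
            )
        arr = arr[..., channel]
    if arr.ndim != 2:
        raise ValueError(f"{path.name}: expected a 2D image, got shape {arr.shape}")
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(np.float32) / np.iinfo(arr.dtype).max
    else:
        arr = arr.astype(np.float32)
    return arr


def write_image(path: str | Path, image: np.ndarray) -> None:
    """Write a float image as float32 TIFF, or 8-bit PNG preview."""
    path = Path(path)
    image = np.asarray(image, dtype=np.float32)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, image)
    else:
        iio.imwrite(path, (np.clip(image, 0, 1) * 255).astype(np.uint8))


def read_mask(path: str | Path) -> np.ndarray:
    """Read an 8-bit mask TIFF/PNG as a boolean grid."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    if arr.ndim != 2:
        raise ValueError(f"{path.name}: mask must be single-channel")
    return arr > 0


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    """Write a boolean grid as an 8-bit {0, 255} TIFF/PNG."""
    path = Path(path)
    data = (np.asarray(mask, dtype=bool) * np.uint8(255))
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, data)
    else:
        iio.imwrite(path, data)


def read_table(path: str | Path, required_columns: list[str]) -> pd.DataFrame:
    """Read a CSV and validate that the named columns are present."""
    df = pd.read_csv(path)
    missing = set(required_columns) - set(df.columns)
    if missing:
        raise ValueError(f"{Path(path).name} missing columns: {sorted(missing)}")
    return df


def write_table(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False)


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_json(path: str | Path, obj) -> None:
    with open(path, "w") as f:
        json.dump(obj, f, indent=2, sort_keys=True, default=_json_default)
        f.write("\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")
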