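"""Reading/writing of section images and binary labeling maps."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

from .errors import DimensionalityError

__all__ = ["read_rgb", "write_rgb", "write_map_gif", "read_map", "write_map_png"]


def read_rgb(path: str | Path) -> np.ndarray:
    """Read an 8-bit RGB section image (TIFF or PNG) as an HxWx3 uint8 array."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path).convert("RGB"))
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[-1] == 4:  # drop alpha
        arr = arr[..., :3]
    if arr.ndim != 3 or arr.shape[-1] != 3:
        raise DimensionalityError(f"{path}: expected an RGB image, got shape {arr.shape}")
    return arr.astype(np.uint8)


def write_rgb(path: str | Path, rgb: np.ndarray) -> None:
    path = Path(path)
    rgb = np.asarray(rgb, dtype=np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, rgb, photometric="rgb")
    else:
        Image.fromarray(rgb, mode="RGB").save(path)


def write_map_gif(path: str | Path, mask: np.ndarray) -> None:
    """Save a binary labeling map losslessly as a 1-bit GIF."""
    Image.fromarray(np.asarray(mask, dtype=bool)).convert("1").save(Path(path), format="GIF")


def write_map_png(path: str | Path, mask: np.ndarray) -> None:
    Image.fromarray(np.asarray(mask, dtype=bool)).convert("1").save(Path(path), format="PNG")


def read_map(path: str | Path) -> np.ndarray:
    """Read a binary labeling map (GIF/PNG) back as a boolean array."""
    return np.asarray(Image.open(path).convert("L")) > 127
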