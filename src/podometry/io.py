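"""File I/O helpers: TIFF images, label masks, tables and configs."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "save_image", "load_image", "save_labels", "load_labels",
    "save_stack", "load_stack", "load_yaml", "save_yaml",
]


def save_image(path: str | Path, image: np.ndarray) -> None:
    """Write a float image in [0, 1] as 16-bit TIFF."""
    arr = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    tifffile.imwrite(str(path), (arr * 65535).round().astype(np.uint16))


def load_image(path: str | Path) -> np.ndarray:
    """Read a 16-bit TIFF back to float in [0, 1]."""
    arr = tifffile.imread(str(path))
    return arr.astype(np.float64) / 65535.0


def save_labels(path: str | Path, labels: np.ndarray) -> None:
    tifffile.imwrite(str(path), np.asarray(labels).astype(np.int32))


def load_labels(path: str | Path) -> np.ndarray:
    return tifffile.imread(str(path)).astype(np.int32)


def save_stack(path: str | Path, stack: np.ndarray) -> None:
    """Write a (depth, H, W) float stack as a multi-page 16-bit TIFF."""
    arr = np.clip(np.asarray(stack, dtype=float), 0.0, 1.0)
    tifffile.imwrite(str(path), (arr * 65535).round().astype(np.uint16))


def load_stack(path: str | Path) -> np.ndarray:
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[None]
    return arr.astype(np.float64) / 65535.0


def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def save_yaml(path: str | Path, data: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
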