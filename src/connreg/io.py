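"""Reading and writing images, masks, float fields and plain-text configs.

Conventions: binary masks travel as 8-bit PNG with {0, 255}; soft fields and
feature maps as 32-bit float TIFF (channels last); configs as flat YAML with
a versioned ``schema`` field; metric reports and run metadata as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
import yaml

from .kernels import Kernel
from .solvers import RegularizerSpec, SolverOptions
from .twophase import TwoPhaseConfig

__all__ = [
    "load_image",
    "load_mask",
    "save_mask_png",
    "save_image_png",
    "load_float_tiff",
    "save_float_tiff",
    "load_config",
    "save_config",
    "write_json",
]

SCHEMA_VERSION = 1


def load_image(path: str | Path) -> np.ndarray:
    """Load a grayscale image (PNG/TIFF) as floats normalized to [0, 1]."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    arr = np.asarray(arr, dtype=float)
    if arr.ndim == 3:  # collapse RGB(A) to luminance
        arr = arr[..., :3].mean(axis=2)
    if arr.max() > 1.0:
        arr = arr / 255.0 if arr.max() <= 255 else arr / arr.max()
    return np.clip(arr, 0.0, 1.0)


def load_mask(path: str | Path) -> np.ndarray:
    """Load a binary mask: any value above half range counts as foreground."""
    arr = iio.imread(Path(path))
    arr = np.asarray(arr)
    if arr.ndim == 3:
        arr = arr[..., 0]
    cut = 0.5 if arr.dtype.kind == "f" else (np.iinfo(arr.dtype).max / 2 if arr.dtype.kind == "u" else 0.5)
    return arr > cut


def save_mask_png(path: str | Path, mask: np.ndarray) -> None:
    iio.imwrite(Path(path), (np.asarray(mask, dtype=bool) * np.uint8(255)))


def save_image_png(path: str | Path, image: np.ndarray) -> None:
    """Save a [0, 1] float image as 8-bit grayscale PNG."""
    arr = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    iio.imwrite(Path(path), np.round(arr * 255).astype(np.uint8))


def load_float_tiff(path: str | Path) -> np.ndarray:
    arr = tifffile.imread(Path(path))
    arr = np.asarray(arr, dtype=float)
    # tifffile stores multi-channel planes first; move channels last
    if arr.ndim == 3 and arr.shape[0] <= 8 and arr.shape[0] < arr.shape[2]:
        arr = np.moveaxis(arr, 0, 2)
    return arr


def save_float_tiff(path: str | Path, field: np.ndarray) -> None:
    arr = np.asarray(field, dtype=np.float32)
    if arr.ndim == 3:
        arr = np.moveaxis(arr, 2, 0)
    tifffile.imwrite(Path(path), arr)


_SECTION_TYPES = {
    "regularizer": RegularizerSpec,
    "solver": SolverOptions,
    "two_phase": TwoPhaseConfig,
    "kernel": Kernel,
}


def save_config(path: str | Path, **sections) -> None:
    """Write named config sections (regularizer=, solver=, two_phase=, kernel=) as YAML."""
    doc: dict = {"schema": SCHEMA_VERSION}
    for name, obj in sections.items():
        if name not in _SECTION_TYPES:
            raise ValueError(f"unknown config section {name!r}")
        doc[name] = obj.to_config()
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_config(path: str | Path) -> dict:
    """Load a YAML config; known sections come back as their domain objects."""
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict):
        raise ValueError("config file must hold a mapping")
    out: dict = {"schema": doc.get("schema", SCHEMA_VERSION)}
    for name, cls in _SECTION_TYPES.items():
        if name in doc:
            out[name] = cls.from_config(doc[name])
    return out


def write_json(path: str | Path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
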