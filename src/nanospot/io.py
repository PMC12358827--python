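"""File round-trips: 16-bit TIFF rasters, CSV tables, YAML configs."""

from __future__ import annotations

from dataclasses import asdict, is_dataclass
from pathlib import Path

import numpy as np
import tifffile
import yaml


def write_tiff(path, image: np.ndarray) -> None:
    """Write an intensity raster as single-channel 16-bit TIFF (clipped)."""
    arr = np.clip(np.rint(np.asarray(image, dtype=float)), 0, 65535)
    tifffile.imwrite(str(path), arr.astype(np.uint16))


def read_tiff(path) -> np.ndarray:
    return tifffile.imread(str(path))


def write_yaml(path, obj) -> None:
    if is_dataclass(obj) and not isinstance(obj, type):
        obj = asdict(obj)
    Path(path).write_text(yaml.safe_dump(_plain(obj), sort_keys=False))


def read_yaml(path):
    return yaml.safe_load(Path(path).read_text())


def _plain(obj):
    """Recursively coerce numpy scalars / tuples for YAML serialization."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj
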