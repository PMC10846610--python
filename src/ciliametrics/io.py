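"""Shared image and metadata I/O.

Images and stacks are read and written as TIFF (16-bit unsigned,
ImageJ-compatible multi-page for stacks) via tifffile, or as PNG via
Pillow. Embedded resolution metadata is surfaced alongside the pixel data
but never silently trusted over user-supplied calibration.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["read_image", "write_tiff", "write_json_sidecar", "read_json"]


def read_image(path: str | Path, allow_rgb: bool = False) -> tuple[np.ndarray, dict]:
    """Read a TIFF or PNG into a grayscale array (or stack) plus metadata.

    Multi-page TIFFs come back as (frames, rows, cols) stacks. RGB images
    are refused unless ``allow_rgb`` is set, in which case they are
    converted to grayscale by channel averaging.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta: dict = {"path": str(path)}
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            data = tf.asarray()
            page = tf.pages[0]
            res = page.tags.get("XResolution")
            if res is not None:
                num, den = res.value
                if num:
                    meta["embedded_um_per_px"] = den / num
    elif suffix == ".png":
        from PIL import Image

        data = np.asarray(Image.open(path))
    else:
        raise ValueError(f"unsupported image format: {path.suffix!r} (use TIFF or PNG)")

    if data.ndim == 3 and data.shape[-1] in (3, 4):
        if not allow_rgb:
            raise ValueError(
                f"{path} is an RGB image; pass allow_rgb=True to average channels"
            )
        data = data[..., :3].mean(axis=-1)
    if data.ndim not in (2, 3):
        raise ValueError(f"unsupported image dimensionality {data.ndim}")
    meta["shape"] = data.shape
    meta["dtype"] = str(data.dtype)
    return data, meta


def write_tiff(path: str | Path, image: np.ndarray, um_per_px: float | None = None) -> None:
    """Write an image or stack as 16-bit unsigned ImageJ-compatible TIFF.

    Float data is clipped at 0 and rounded; values above 65535 saturate.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arr = np.asarray(image)
    if arr.dtype != np.uint16:
        arr = np.clip(np.rint(arr), 0, 65535).astype(np.uint16)
    kwargs: dict = {"imagej": True}
    if um_per_px is not None:
        kwargs["resolution"] = (1.0 / um_per_px, 1.0 / um_per_px)
        kwargs["metadata"] = {"unit": "um"}
    tifffile.imwrite(path, arr, **kwargs)


def write_json_sidecar(path: str | Path, payload: dict) -> None:
    """Write a params/calibration sidecar next to an image or table."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=_jsonable)


def read_json(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
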