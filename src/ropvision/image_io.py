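"""Raster I/O with strict 8-bit RGB semantics.

Wide-field fundus photographs enter the pipeline as 8-bit RGB arrays; every
intermediate single-channel working image (raw green plane, noise-filtered
plane, enhanced plane G') is carried in floating point on the 0-255 scale and
only quantized when written to disk.  Lossless containers (PNG, uncompressed
TIFF) are used for all protocol outputs so that round-trips are bit-exact.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import imageio.v3 as iio
import numpy as np

__all__ = [
    "GreyPlane",
    "read_image",
    "write_image",
    "quantize_u8",
    "validate_rgb",
    "write_metadata",
    "read_metadata",
]

#: allowed processing-stage tags for a grey working plane
STAGES = ("raw_green", "filtered", "enhanced")


@dataclass
class GreyPlane:
    """Single-channel working image on the 0-255 intensity scale.

    Parameters
    ----------
    values : ndarray of float, shape (H, W)
        Intensities.  Finite, nominally in [0, 255]; quantized on export only.
    stage : {'raw_green', 'filtered', 'enhanced'}
        Which pipeline stage produced the plane.
    """

    values: np.ndarray
    stage: str = "raw_green"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("GreyPlane requires a non-empty 2-D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("GreyPlane values must be finite")
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {STAGES}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]


def quantize_u8(values: np.ndarray) -> np.ndarray:
    """Quantize real intensities to uint8: round half up, then clamp to [0, 255].

    Idempotent on already-integral input.
    """
    v = np.asarray(values, dtype=np.float64)
    return np.clip(np.floor(v + 0.5), 0.0, 255.0).astype(np.uint8)


def validate_rgb(image: np.ndarray) -> np.ndarray:
    """Check an array is a valid 8-bit H×W×3 RGB image and return it as uint8."""
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an H×W×3 RGB array, got shape {img.shape}")
    if img.shape[0] == 0 or img.shape[1] == 0:
        raise ValueError("zero-area image")
    if img.dtype != np.uint8:
        if not np.issubdtype(img.dtype, np.integer):
            raise ValueError(f"RGB image must be integer-typed, got {img.dtype}")
        if img.min() < 0 or img.max() > 255:
            raise ValueError("RGB intensities must lie in [0, 255]")
        img = img.astype(np.uint8)
    return img


def read_image(path: str | os.PathLike) -> np.ndarray:
    """Read a PNG/TIFF/JPEG file as an 8-bit RGB array.

    Greyscale sources are replicated across the three channels, alpha channels
    are dropped, and 16-bit sources are linearly rescaled to [0, 255].
    """
    path = os.fspath(path)
    try:
        arr = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # noqa: BLE001 - normalise backend errors
        raise OSError(f"could not read image file {path!r}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.size == 0:
        raise ValueError(f"zero-area image in {path!r}")
    if arr.dtype == np.uint16:
        arr = quantize_u8(arr.astype(np.float64) * (255.0 / 65535.0))
    elif arr.dtype == bool:
        arr = arr.astype(np.uint8) * 255
    elif arr.dtype != np.uint8:
        raise ValueError(f"unsupported pixel type {arr.dtype} in {path!r}")
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    elif arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    return validate_rgb(arr)


def write_image(image: np.ndarray | GreyPlane, path: str | os.PathLike) -> None:
    """Write an RGB image, grey plane, or vesselness map to disk.

    2-D inputs (grey planes, vesselness maps) are written as single-channel
    files; floating-point planes are quantized (round half up, clamp) first.
    """
    path = os.fspath(path)
    parent = os.path.dirname(path) or "."
    if not os.path.isdir(parent):
        raise OSError(f"parent directory does not exist for {path!r}")
    if isinstance(image, GreyPlane):
        arr = quantize_u8(image.values)
    else:
        arr = np.asarray(image)
        if np.issubdtype(arr.dtype, np.floating):
            arr = quantize_u8(arr)
        elif arr.dtype == bool:
            arr = arr.astype(np.uint8) * 255
        elif arr.dtype != np.uint8:
            arr = quantize_u8(arr.astype(np.float64))
    if arr.ndim == 3:
        arr = validate_rgb(arr)
    try:
        iio.imwrite(path, arr)
    except Exception as exc:  # noqa: BLE001
        raise OSError(f"could not write image file {path!r}: {exc}") from exc


def write_metadata(path: str | os.PathLike, meta: dict) -> None:
    """Write sidecar session metadata as ``key = value`` lines."""
    with open(path, "w", encoding="utf-8") as fh:
        for key, value in meta.items():
            if "=" in str(key):
                raise ValueError(f"metadata key may not contain '=': {key!r}")
            fh.write(f"{key} = {value}\n")


def read_metadata(path: str | os.PathLike) -> dict:
    """Read a sidecar metadata file written by :func:`write_metadata`."""
    meta: dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            meta[key.strip()] = value.strip()
    return meta
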