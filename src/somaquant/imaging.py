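"""Image/mask/ROI data model and I/O shared by the whole pipeline.

Conventions
-----------
* Pixels are stored as ``float`` arrays of shape ``(H, W, C)`` with intensities
  normalised to ``[0, 1]``; the raw bit depth is kept in ``meta['bit_depth']``
  so integer data round-trips exactly.
* Coordinates are 0-based; ``x`` is the column index (increasing rightward) and
  ``y`` the row index (increasing downward).  Polygon vertices live in the same
  pixel-centre coordinate system.
* Channel roles (marker / target / nuclear / brightfield) are carried by name,
  not by position; callers address channels through ``channel_index``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import imageio.v3 as iio
import tifffile
from shapely.geometry import Point, Polygon

__all__ = [
    "MultiChannelImage",
    "LabelMask",
    "ROIPolygon",
    "load_image",
    "write_image",
    "load_mask",
    "write_mask",
    "max_project",
    "point_in_roi",
]

MAX_CHANNELS = 4


@dataclass
class MultiChannelImage:
    """A 2-D multi-channel image with named channels and physical pixel size."""

    pixels: np.ndarray  # (H, W, C) float in [0, 1]
    channel_names: list[str]
    pixel_size_um: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim == 2:
            self.pixels = self.pixels[:, :, None]
        if self.pixels.ndim != 3:
            raise ValueError("pixels must be H x W x C")
        h, w, c = self.pixels.shape
        if h < 1 or w < 1:
            raise ValueError("image must have at least one pixel")
        if not 1 <= c <= MAX_CHANNELS:
            raise ValueError(f"channel count must be in 1..{MAX_CHANNELS}, got {c}")
        if len(self.channel_names) != c:
            raise ValueError(
                f"{len(self.channel_names)} channel names for {c} channels"
            )
        if len(set(self.channel_names)) != c:
            raise ValueError("channel names must be unique")
        if not np.all(np.isfinite(self.pixels)) or np.any(self.pixels < 0):
            raise ValueError("intensities must be finite and non-negative")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[2]

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"unknown channel {name!r}; have {self.channel_names}")

    def channel(self, name: str) -> np.ndarray:
        return self.pixels[:, :, self.channel_index(name)]

    def copy(self) -> "MultiChannelImage":
        return MultiChannelImage(
            self.pixels.copy(), list(self.channel_names), self.pixel_size_um,
            dict(self.meta),
        )


@dataclass
class LabelMask:
    """Integer mask aligned to an image; 0 is background.

    ``kind`` distinguishes semantic masks (label = class id, with
    ``class_names``) from instance masks (label = object id).
    """

    labels: np.ndarray
    kind: str = "semantic"  # "semantic" | "instance"
    class_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be a 2-D array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integer")
        if self.labels.min(initial=0) < 0:
            raise ValueError("labels must be >= 0")
        if self.kind not in ("semantic", "instance"):
            raise ValueError("kind must be 'semantic' or 'instance'")
        if self.kind == "semantic":
            if self.class_names is None:
                raise ValueError("semantic masks need class_names")
            if self.labels.max(initial=0) >= len(self.class_names):
                raise ValueError("semantic label exceeds number of classes")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape


@dataclass
class ROIPolygon:
    """A named polygonal region of interest in pixel coordinates."""

    vertices: list[tuple[float, float]]
    name: str = "ROI"
    hemisphere: str = "none"  # "left" | "right" | "none"

    def __post_init__(self) -> None:
        self.vertices = [(float(x), float(y)) for x, y in self.vertices]
        if len(self.vertices) < 3:
            raise ValueError("polygon needs at least 3 vertices")
        if self.hemisphere not in ("left", "right", "none"):
            raise ValueError("hemisphere must be left/right/none")
        poly = Polygon(self.vertices)
        if not poly.is_valid or poly.area == 0:
            raise ValueError("polygon must be simple and non-degenerate")

    def as_shapely(self) -> Polygon:
        return Polygon(self.vertices)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "name": self.name,
            "hemisphere": self.hemisphere,
            "vertices": [list(v) for v in self.vertices],
        }))

    @classmethod
    def from_json(cls, path: str | Path) -> "ROIPolygon":
        d = json.loads(Path(path).read_text())
        return cls(vertices=[tuple(v) for v in d["vertices"]],
                   name=d.get("name", "ROI"),
                   hemisphere=d.get("hemisphere", "none"))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _normalise(raw: np.ndarray) -> tuple[np.ndarray, int]:
    """Scale integer pixel data to float [0, 1]; return (float array, bit depth)."""
    if np.issubdtype(raw.dtype, np.floating):
        return raw.astype(float), 0
    bits = raw.dtype.itemsize * 8
    return raw.astype(float) / float(2 ** bits - 1), bits


def _to_hwc(raw: np.ndarray, n_channels: int) -> np.ndarray:
    if raw.ndim == 2:
        raw = raw[:, :, None]
    elif raw.ndim == 3 and raw.shape[0] in (1, 2, 3, 4) and raw.shape[2] not in (1, 2, 3, 4):
        # channel-first TIFF plane
        raw = np.moveaxis(raw, 0, 2)
    if raw.shape[2] != n_channels:
        raise ValueError(
            f"file has {raw.shape[2]} channels but {n_channels} names given"
        )
    return raw


def load_image(path: str | Path, channel_names: Sequence[str],
               pixel_size_um: float = 1.0):
    """Read a TIFF or PNG image (or a multi-page TIFF z-stack).

    Returns a :class:`MultiChannelImage`, or a list of them for a z-stack.
    Integer intensities are scaled to [0, 1] by the full range of the bit
    depth; the depth is recorded in ``meta['bit_depth']``.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    names = list(channel_names)
    suffix = path.suffix.lower()
    try:
        if suffix in (".tif", ".tiff"):
            raw = tifffile.imread(str(path))
        else:
            raw = np.asarray(iio.imread(str(path)))
    except Exception as exc:  # pragma: no cover - corrupt-file path
        raise IOError(f"cannot read {path}: {exc}") from exc

    # Disambiguate a 3-D TIFF: a single H x W x C (or C x H x W) frame when one
    # axis matches the channel count, otherwise a z-stack of 2-D planes.
    if raw.ndim == 3 and suffix in (".tif", ".tiff"):
        is_stack = not (raw.shape[2] == len(names) or raw.shape[0] == len(names))
        if len(names) == 1 and raw.shape[2] != 1 and raw.shape[0] != 1:
            is_stack = True
    else:
        is_stack = raw.ndim == 4
    if is_stack:
        planes = []
        for plane in raw:
            arr = _to_hwc(np.asarray(plane), len(names))
            data, bits = _normalise(arr)
            planes.append(MultiChannelImage(
                data, names, pixel_size_um, {"bit_depth": bits, "path": str(path)}))
        return planes

    arr = _to_hwc(raw, len(names))
    data, bits = _normalise(arr)
    return MultiChannelImage(data, names, pixel_size_um,
                             {"bit_depth": bits, "path": str(path)})


def write_image(path: str | Path, image: MultiChannelImage,
                bit_depth: int | None = None) -> None:
    """Write an image as TIFF or PNG, restoring the recorded bit depth.

    Inverse of :func:`load_image` on integer data: quantisation uses the same
    full-scale factor, so load -> write -> load is the identity.
    """
    path = Path(path)
    bits = bit_depth or image.meta.get("bit_depth") or 8
    scale = float(2 ** bits - 1)
    arr = np.round(np.clip(image.pixels, 0, 1) * scale)
    arr = arr.astype(np.uint8 if bits <= 8 else np.uint16)
    if arr.shape[2] == 1:
        arr = arr[:, :, 0]
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(str(path), arr)
    else:
        iio.imwrite(str(path), arr)


def load_mask(path: str | Path, kind: str = "instance",
              class_names: list[str] | None = None) -> LabelMask:
    """Read a 16-bit single-channel TIFF label mask."""
    raw = tifffile.imread(str(path))
    return LabelMask(raw.astype(np.int64), kind=kind, class_names=class_names)


def write_mask(path: str | Path, mask: LabelMask) -> None:
    if mask.labels.max(initial=0) > np.iinfo(np.uint16).max:
        raise ValueError("labels exceed 16-bit range")
    tifffile.imwrite(str(path), mask.labels.astype(np.uint16))


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def max_project(stack: Sequence[MultiChannelImage]) -> MultiChannelImage:
    """Maximum-intensity z-projection of a stack of aligned planes."""
    if len(stack) == 0:
        raise ValueError("empty stack")
    first = stack[0]
    for plane in stack[1:]:
        if plane.pixels.shape != first.pixels.shape:
            raise ValueError("all planes must share the same shape")
        if plane.channel_names != first.channel_names:
            raise ValueError("all planes must share the same channels")
    out = np.max(np.stack([p.pixels for p in stack]), axis=0)
    return MultiChannelImage(out, list(first.channel_names), first.pixel_size_um,
                             {**first.meta, "z_planes": len(stack)})


def point_in_roi(roi: ROIPolygon, point: tuple[float, float]) -> bool:
    """Even-odd polygon membership; points on the boundary count as inside."""
    return bool(roi.as_shapely().covers(Point(point)))
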