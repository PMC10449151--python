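"""Image, mask and table I/O.

Images are exchanged as PNG/BMP/JPEG and held in memory as RGB float rasters
in [0, 1] (row, col indexing, origin top-left); binary masks as 8-bit PNG with
values {0, 255}; tables as RFC-4180 CSV with a header row; manifests and model
files as JSON.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from skimage import transform

__all__ = [
    "RetinalImage",
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "widths_to_frame",
    "write_widths_csv",
    "write_centreline_csv",
]


@dataclass
class RetinalImage:
    """Colour fundus raster plus provenance.

    ``data`` is (H, W, 3) float in [0, 1] at the working resolution;
    ``original_size`` is the (height, width) of the file as read.
    """

    data: np.ndarray
    path: str | None = None
    original_size: tuple[int, int] | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[:2]


def _working_shape(shape: tuple[int, int], long_side: int) -> tuple[int, int]:
    h, w = shape
    if max(h, w) <= long_side:
        return (h, w)
    scale = long_side / max(h, w)
    if h >= w:
        return (long_side, round(w * scale))
    return (round(h * scale), long_side)


def read_image(path, working_long_side: int | None = None) -> RetinalImage:
    """Read a PNG/BMP/JPEG fundus image as an RGB float raster in [0, 1].

    When ``working_long_side`` is given and the image is larger, it is
    resized (aspect preserved) so its longer side equals that value.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            rgb = np.asarray(im.convert("RGB"), dtype=float) / 255.0
    except OSError as exc:
        raise OSError(f"cannot read image file {path}: {exc}") from exc
    original = rgb.shape[:2]
    if working_long_side is not None:
        target = _working_shape(original, working_long_side)
        if target != original:
            rgb = transform.resize(rgb, target, order=1, anti_aliasing=True)
    return RetinalImage(data=rgb, path=str(path), original_size=original)


def write_image(image: np.ndarray | RetinalImage, path) -> None:
    """Write a float raster in [0, 1] as an 8-bit PNG/BMP."""
    data = image.data if isinstance(image, RetinalImage) else np.asarray(image)
    arr = np.clip(np.round(data * 255), 0, 255).astype(np.uint8)
    Image.fromarray(arr).save(path)


def read_mask(path) -> np.ndarray:
    with Image.open(path) as im:
        return np.asarray(im.convert("L")) > 127


def write_mask(mask, path) -> None:
    data = mask.data if (hasattr(mask, "data") and not isinstance(mask, np.ndarray)) \
        else np.asarray(mask)
    Image.fromarray((data.astype(np.uint8)) * 255).save(path)


_WIDTH_COLUMNS = ["x", "y", "orientation_rad", "edge_lx", "edge_ly",
                  "edge_rx", "edge_ry", "width_px", "valid", "reject_reason",
                  "segment_id"]


def widths_to_frame(measurements) -> pd.DataFrame:
    """Width measurements as a table (x = column, y = row, as in image viewers)."""
    rows = []
    for m in measurements:
        el = m.edge_left or (np.nan, np.nan)
        er = m.edge_right or (np.nan, np.nan)
        rows.append({
            "x": m.centre[1], "y": m.centre[0],
            "orientation_rad": m.orientation,
            "edge_lx": el[1], "edge_ly": el[0],
            "edge_rx": er[1], "edge_ry": er[0],
            "width_px": m.width, "valid": m.valid,
            "reject_reason": m.reject_reason or "",
            "segment_id": m.segment_id,
        })
    return pd.DataFrame(rows, columns=_WIDTH_COLUMNS)


def write_widths_csv(measurements, path) -> None:
    widths_to_frame(measurements).to_csv(path, index=False)


def write_centreline_csv(truth, path) -> None:
    """Ground-truth centreline table: x, y, width_px, av_label, segment_id."""
    rows = [{"x": p.col, "y": p.row, "width_px": p.width,
             "av_label": p.av_label, "segment_id": p.segment_id}
            for p in truth.centreline_points]
    pd.DataFrame(rows, columns=["x", "y", "width_px", "av_label",
                                "segment_id"]).to_csv(path, index=False)
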