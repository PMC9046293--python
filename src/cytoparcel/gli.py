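"""Grey level index (GLI) images.

The GLI measures the volume fraction of cell bodies inside a small square
measuring field (16 × 16 µm² by default) of a segmented cell-stained
section: each GLI value is (cell pixels in field) / (pixels in field).
Values are kept as exact fractions internally; the classical 8-bit form is
an export, not the computation substrate, so downstream statistics never see
quantization error.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["GliImage", "compute_gli", "export_gli_8bit", "import_gli_8bit",
           "save_gli", "load_gli"]


@dataclass
class GliImage:
    """Grid of cell-body volume fractions per measuring field.

    ``values[i, j]`` covers source pixels ``[i*f:(i+1)*f, j*f:(j+1)*f]``
    where ``f = field_size_um / pixel_size_um``; edge fields may be smaller
    and are normalized by their actual pixel count.
    """

    values: np.ndarray
    field_size_um: float
    pixel_size_um: float

    @property
    def field_px(self) -> int:
        return int(round(self.field_size_um / self.pixel_size_um))

    def to_image_coords(self, gli_xy: np.ndarray) -> np.ndarray:
        """Map GLI grid (x, y) coordinates to source-image pixel coords."""
        f = self.field_px
        return (np.asarray(gli_xy, float) + 0.5) * f - 0.5

    def to_gli_coords(self, image_xy: np.ndarray) -> np.ndarray:
        """Map source-image pixel (x, y) coordinates to GLI grid coords."""
        f = self.field_px
        return (np.asarray(image_xy, float) + 0.5) / f - 0.5


def compute_gli(section, field_size_um: float = 16.0) -> GliImage:
    """Convert a segmented section into a GLI image.

    The field size must be an integer multiple of the pixel size; each field
    value is the fraction of cell pixels it contains, with partial fields at
    the right/bottom edges normalized by their actual pixel count so that
    ``sum(value * field_pixel_count)`` conserves the total cell pixel count
    exactly.
    """
    mask = np.asarray(section.mask)
    if mask.size == 0:
        raise ValueError("empty image")
    uniq = np.unique(mask)
    if not np.all(np.isin(uniq, [0, 1])):
        raise ValueError("mask must be binary")
    ratio = field_size_um / section.pixel_size_um
    f = int(round(ratio))
    if abs(ratio - f) > 1e-9 or f < 1:
        raise ValueError(
            "field size must be an integer multiple of the pixel size"
        )
    h, w = mask.shape
    m = mask.astype(np.float64)
    row_edges = np.arange(0, h, f)
    col_edges = np.arange(0, w, f)
    sums = np.add.reduceat(np.add.reduceat(m, row_edges, axis=0), col_edges, axis=1)
    rows = np.minimum(row_edges + f, h) - row_edges
    cols = np.minimum(col_edges + f, w) - col_edges
    counts = np.outer(rows, cols).astype(np.float64)
    return GliImage(values=sums / counts, field_size_um=field_size_um,
                    pixel_size_um=section.pixel_size_um)


def export_gli_8bit(gli: GliImage) -> np.ndarray:
    """Export GLI fractions as 8-bit grey values, v -> round(v * 255).

    Rounding is round-half-up (0.5 maps to 128).  Display inversion (dark =
    cell dense) is a rendering choice and is not applied here.
    """
    v = np.asarray(gli.values, float)
    return np.floor(v * 255.0 + 0.5).astype(np.uint8)


def import_gli_8bit(img: np.ndarray, field_size_um: float,
                    pixel_size_um: float) -> GliImage:
    """Rebuild a GliImage from its 8-bit export (quantized to 1/255)."""
    return GliImage(values=np.asarray(img, float) / 255.0,
                    field_size_um=field_size_um, pixel_size_um=pixel_size_um)


def save_gli(gli: GliImage, path: str | Path, as_8bit: bool = False) -> None:
    """Write the GLI grid as TIFF (float32 by default, uint8 on request)."""
    import tifffile

    data = export_gli_8bit(gli) if as_8bit else gli.values.astype(np.float32)
    tifffile.imwrite(str(path), data)


def load_gli(path: str | Path, field_size_um: float,
             pixel_size_um: float) -> GliImage:
    """Read a GLI TIFF written by :func:`save_gli`."""
    import tifffile

    data = tifffile.imread(str(path))
    if data.dtype == np.uint8:
        return import_gli_8bit(data, field_size_um, pixel_size_um)
    return GliImage(values=np.asarray(data, np.float64),
                    field_size_um=field_size_um, pixel_size_um=pixel_size_um)
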