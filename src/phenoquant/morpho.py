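"""Morphometrics: trichome counting and silhouette body measurements.

Trichomes — the cuticular hairs whose pattern reads out the svb pathway —
appear in phase-contrast cuticle preparations as punctate maxima; they are
counted inside user-supplied anatomical ROIs with a prominence-based
maxima detector (prominence, the height of a peak above its highest
surrounding saddle, is robust to uneven illumination). Body size is
measured from thresholded silhouettes: area as pixel count times pixel
area, length as the major axis of the second-moment ellipse.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import regionprops, label as sk_label
from skimage.morphology import h_maxima

__all__ = [
    "Image2D",
    "ROI",
    "TrichomeParams",
    "count_trichomes",
    "body_metrics",
    "read_image",
    "write_image",
]


@dataclass
class Image2D:
    data: np.ndarray
    pixel_size_mm: float | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.size == 0:
            raise ValueError("Image2D requires a non-empty 2D array")
        if self.pixel_size_mm is not None and self.pixel_size_mm <= 0:
            raise ValueError("pixel size must be positive")


@dataclass
class ROI:
    """Region of interest as a binary mask on the image grid."""

    mask: np.ndarray
    name: str = "roi"

    def __post_init__(self):
        self.mask = np.asarray(self.mask).astype(bool)

    @classmethod
    def from_polygon(cls, vertices, shape, name: str = "roi") -> "ROI":
        from skimage.draw import polygon

        rr, cc = polygon([v[0] for v in vertices], [v[1] for v in vertices],
                         shape)
        m = np.zeros(shape, dtype=bool)
        m[rr, cc] = True
        return cls(m, name)

    @classmethod
    def full(cls, shape, name: str = "full") -> "ROI":
        return cls(np.ones(shape, dtype=bool), name)


@dataclass
class TrichomeParams:
    min_prominence: float = 10.0
    min_separation_px: float = 3.0


def count_trichomes(image: Image2D, roi: ROI,
                    params: TrichomeParams | None = None
                    ) -> tuple[int, np.ndarray]:
    """Count punctate maxima (trichomes) inside an ROI.

    Maxima with prominence >= ``min_prominence`` are located (via
    h-maxima morphological reconstruction, so an additive intensity
    offset cannot change the result), reduced to one coordinate per
    plateau, restricted to the ROI, and non-maximum-suppressed at
    ``min_separation_px`` keeping the brighter punctum. Returns
    ``(count, (n, 2) array of (row, col) coordinates)``; deterministic.
    """
    params = params or TrichomeParams()
    if roi.mask.shape != image.data.shape:
        raise ValueError("ROI shape must match image shape")
    if not roi.mask.any():
        raise ValueError(f"ROI {roi.name!r} is empty")
    hmax = h_maxima(image.data, params.min_prominence)
    lab, n = ndimage.label(hmax)
    if n == 0:
        return 0, np.empty((0, 2), dtype=int)
    # one representative (peak-plateau centroid) per maximum
    coords = np.array(ndimage.center_of_mass(hmax, lab, np.arange(1, n + 1)))
    coords = np.round(coords).astype(int)
    vals = image.data[coords[:, 0], coords[:, 1]]
    inside = roi.mask[coords[:, 0], coords[:, 1]]
    coords, vals = coords[inside], vals[inside]
    # NMS, brighter first; ties to earlier (row, col)
    order = np.lexsort((coords[:, 1], coords[:, 0], -vals))
    coords = coords[order]
    kept: list[int] = []
    min_sep2 = params.min_separation_px ** 2
    for i, c in enumerate(coords):
        if kept and np.min(((coords[kept] - c) ** 2).sum(axis=1)) < min_sep2:
            continue
        kept.append(i)
    out = coords[kept]
    return len(out), out


def body_metrics(image: Image2D, threshold: float | None = None
                 ) -> dict[str, float]:
    """Area (mm²) and length (mm) of the largest foreground component.

    The silhouette is thresholded (Otsu unless ``threshold`` is given);
    area is the component's pixel count times the pixel area; length is
    the major-axis length of its second-moment ellipse.
    """
    if image.pixel_size_mm is None:
        raise ValueError("body_metrics requires a calibrated pixel size")
    data = image.data
    thr = threshold if threshold is not None else threshold_otsu(data)
    fg = data > thr
    lab = sk_label(fg)
    if lab.max() == 0:
        raise ValueError("no foreground component found")
    props = regionprops(lab)
    biggest = max(props, key=lambda p: p.area)
    px = image.pixel_size_mm
    return {
        "area_mm2": float(biggest.area) * px * px,
        "length_mm": float(biggest.axis_major_length) * px,
        "n_pixels": float(biggest.area),
    }


# ---------------------------------------------------------------------------
# I/O

def write_image(image: Image2D, path) -> None:
    import tifffile

    tifffile.imwrite(str(path), image.data.astype(np.float32))
    if image.pixel_size_mm is not None:
        with open(str(path) + ".json", "w") as fh:
            json.dump({"pixel_size_mm": image.pixel_size_mm}, fh)


def read_image(path, pixel_size_mm: float | None = None) -> Image2D:
    import os
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(str(path))).astype(float)
    if arr.ndim == 3:            # drop color axis if present
        arr = arr.mean(axis=-1)
    sidecar = str(path) + ".json"
    if pixel_size_mm is None and os.path.exists(sidecar):
        with open(sidecar) as fh:
            pixel_size_mm = json.load(fh).get("pixel_size_mm")
    return Image2D(arr, pixel_size_mm)
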