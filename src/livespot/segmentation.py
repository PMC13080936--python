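"""Cell masks: watershed segmentation, polygon ROIs, mask import, spot assignment.

Masks are label rasters (0 = background, k > 0 = cell k) that are either
static (one plane applied to every frame) or time-varying (one plane per
frame). Deep-learning segmentation is out of scope; masks exported by
external tools are imported through :func:`import_mask`.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from matplotlib.path import Path as MplPath
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import gaussian
from skimage.segmentation import watershed

__all__ = [
    "CellMask",
    "watershed_segment",
    "polygon_to_mask",
    "import_mask",
    "export_mask",
    "assign_spots_to_cells",
]


@dataclasses.dataclass
class CellMask:
    labels: np.ndarray          # (Y, X) or (T, Y, X) non-negative integers
    frame_varying: bool = False

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        expected_ndim = 3 if self.frame_varying else 2
        if self.labels.ndim != expected_ndim:
            raise ValueError(
                f"{'time-varying' if self.frame_varying else 'static'} mask must have "
                f"{expected_ndim} axes, got {self.labels.ndim}"
            )
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative")

    @property
    def n_cells(self) -> int:
        return int(self.labels.max())

    def plane(self, frame: int) -> np.ndarray:
        """Label plane that applies to ``frame``."""
        return self.labels[frame] if self.frame_varying else self.labels


def _relabel_contiguous(labels: np.ndarray) -> np.ndarray:
    """Renumber labels to 1..K preserving regions (0 stays background)."""
    values = np.unique(labels)
    values = values[values > 0]
    out = np.zeros_like(labels, dtype=np.int32)
    for new, old in enumerate(values, start=1):
        out[labels == old] = new
    return out


def watershed_segment(image: np.ndarray, intensity_threshold: float,
                      min_area_px: int = 50, min_peak_separation_px: int = 10,
                      smoothing_sigma_px: float = 2.0) -> CellMask:
    """Threshold-based watershed segmentation of one 2D image.

    The image is Gaussian-smoothed, thresholded into foreground, and
    touching objects are split by a watershed on the negated distance
    transform seeded at distance-transform maxima separated by at least
    ``min_peak_separation_px``. Regions below ``min_area_px`` are removed
    and labels renumbered from 1.
    """
    if intensity_threshold < 0 or min_area_px < 0:
        raise ValueError("thresholds must be >= 0")
    img = np.asarray(image, dtype=np.float64)
    smoothed = gaussian(img, sigma=smoothing_sigma_px, preserve_range=True)
    foreground = smoothed >= intensity_threshold
    if not foreground.any():
        return CellMask(labels=np.zeros(img.shape, dtype=np.int32))
    distance = ndi.distance_transform_edt(foreground)
    peaks = peak_local_max(distance, min_distance=int(min_peak_separation_px),
                           labels=foreground, exclude_border=False)
    markers = np.zeros(img.shape, dtype=np.int32)
    for i, (y, x) in enumerate(peaks, start=1):
        markers[y, x] = i
    if markers.max() == 0:
        labels, _ = ndi.label(foreground)
    else:
        labels = watershed(-distance, markers, mask=foreground)
    # drop small regions
    sizes = np.bincount(labels.ravel())
    small = np.where(sizes < min_area_px)[0]
    for lab in small:
        if lab > 0:
            labels[labels == lab] = 0
    return CellMask(labels=_relabel_contiguous(labels))


def polygon_to_mask(vertices, shape: tuple[int, int], label: int = 1) -> CellMask:
    """Rasterize an ROI polygon: pixels whose centers fall inside get ``label``."""
    vertices = np.asarray(vertices, dtype=float)
    if vertices.ndim != 2 or vertices.shape[0] < 3 or vertices.shape[1] != 2:
        raise ValueError("a polygon needs at least 3 (y, x) vertices")
    ny, nx = shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    centers = np.column_stack([yy.ravel(), xx.ravel()])
    path = MplPath(vertices)
    inside = path.contains_points(centers).reshape(ny, nx)
    labels = np.where(inside, int(label), 0).astype(np.int32)
    return CellMask(labels=labels)


def import_mask(path: str | Path, shape: tuple[int, int]) -> CellMask:
    """Load a pre-computed label TIFF, renumbering labels contiguously.

    A 2D image yields a static mask; a 3D (T, Y, X) stack a time-varying
    one. The trailing (Y, X) shape must match the movie.
    """
    arr = tifffile.imread(Path(path))
    if arr.ndim not in (2, 3):
        raise ValueError(f"label image must be 2D or 3D, got {arr.ndim} axes")
    if tuple(arr.shape[-2:]) != tuple(shape):
        raise ValueError(f"mask shape {arr.shape[-2:]} does not match movie shape {tuple(shape)}")
    labels = _relabel_contiguous(arr.astype(np.int64))
    return CellMask(labels=labels, frame_varying=arr.ndim == 3)


def export_mask(mask: CellMask, path: str | Path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, mask.labels.astype(np.uint16), photometric="minisblack")
    return path


def assign_spots_to_cells(spots: pd.DataFrame, mask: CellMask) -> pd.DataFrame:
    """Set each spot's ``cell_label`` from the mask at its rounded position.

    Labels are categorical, so nearest-pixel lookup is used rather than
    interpolation; spots outside every cell get label 0. Time-varying
    masks use the plane matching each spot's frame.
    """
    spots = spots.copy()
    if len(spots) == 0:
        return spots
    ny, nx = mask.labels.shape[-2:]
    iy = np.clip(np.rint(spots["y_px"].to_numpy()).astype(int), 0, ny - 1)
    ix = np.clip(np.rint(spots["x_px"].to_numpy()).astype(int), 0, nx - 1)
    if mask.frame_varying:
        frames = spots["frame"].to_numpy().astype(int)
        labels = mask.labels[frames, iy, ix]
    else:
        labels = mask.labels[iy, ix]
    spots["cell_label"] = labels.astype(int)
    return spots
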