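"""Cell and nucleus segmentation and track-to-compartment assignment.

Frame averages of the two fluorescence channels (cell body vs nuclear
marker) are thresholded with a bimodal-histogram (Otsu) method; thresholded
cell masks frequently leave touching cells joined, so a seeded watershed
with the nucleus masks as basins splits them into one region per nucleus.
Tracks are then assigned to a cell and sub-cellular compartment (nucleus,
cytoplasm or outside) from their lateral centroid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.segmentation import watershed

__all__ = [
    "CellMap",
    "frame_average",
    "threshold_masks",
    "watershed_split",
    "assign_tracks",
    "segment_cells",
]

#: default minimum object area, 2 um^2 at 93 nm pixels
MIN_AREA_UM2 = 2.0


@dataclass
class CellMap:
    """Labelled cell and nucleus masks sharing one pixel coordinate frame."""

    cell_labels: np.ndarray
    nucleus_labels: np.ndarray
    pixel_size_nm: float = 93.0
    parent: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.cell_labels.shape != self.nucleus_labels.shape:
            raise ValueError("cell and nucleus masks must share a shape")
        if not self.parent:
            self.parent = self._parents()

    def _parents(self) -> dict[int, int]:
        out = {}
        for n in np.unique(self.nucleus_labels):
            if n == 0:
                continue
            cells = self.cell_labels[self.nucleus_labels == n]
            cells = cells[cells > 0]
            out[int(n)] = int(np.bincount(cells).argmax()) if cells.size else 0
        return out


def frame_average(stack: np.ndarray, n_frames: int = 5) -> np.ndarray:
    """Pixel-wise mean of the first ``n_frames`` frames of a stack."""
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("stack must be (frames, h, w)")
    if len(stack) < n_frames:
        raise ValueError(f"stack has {len(stack)} frames, need {n_frames}")
    return stack[:n_frames].mean(axis=0)


def threshold_masks(
    avg_image: np.ndarray,
    min_area_px: int | None = None,
    pixel_size_nm: float = 93.0,
) -> np.ndarray:
    """Binary foreground mask by Otsu threshold, hole filling and size filter.

    A blank (effectively constant) image yields an empty mask rather than an
    Otsu split of pure noise; the minimum object area defaults to 2 um^2.
    """
    img = np.asarray(avg_image, dtype=float)
    if not np.all(np.isfinite(img)):
        raise ValueError("image must be finite")
    if min_area_px is None:
        min_area_px = int(MIN_AREA_UM2 * 1e6 / pixel_size_nm**2)
    if np.ptp(img) == 0:
        return np.zeros(img.shape, dtype=bool)
    # Otsu, recursively re-applied above the current threshold when the
    # foreground class is too small to separate from the background noise
    # (small nuclei occupy ~1% of the field and defeat plain Otsu).
    thresh = threshold_otsu(img)
    for _ in range(3):
        mask = img > thresh
        if not mask.any() or mask.all():
            return np.zeros(img.shape, dtype=bool)
        bg = img[~mask]
        noise = 1.4826 * np.median(np.abs(bg - np.median(bg)))
        if noise == 0 or (img[mask].mean() - bg.mean()) >= 4.0 * noise:
            break
        upper = img[img > thresh]
        if upper.size < 100 or np.ptp(upper) == 0:
            return np.zeros(img.shape, dtype=bool)
        thresh = threshold_otsu(upper)
    else:
        return np.zeros(img.shape, dtype=bool)
    mask = ndimage.binary_fill_holes(mask)
    if min_area_px > 0:
        labels, n = ndimage.label(mask)
        if n:
            areas = np.bincount(labels.ravel())
            keep = np.flatnonzero(areas >= min_area_px)
            mask = np.isin(labels, keep[keep > 0])
    return mask


def watershed_split(cell_mask: np.ndarray,
                    nucleus_labels: np.ndarray) -> np.ndarray:
    """Split joined cell masks with nucleus labels as watershed seeds.

    The watershed floods the negated Euclidean distance transform of the
    mask from the seed basins, so the number of output labels equals the
    number of seeds and the labels partition the seeded part of the mask
    exactly.  Connected mask regions containing no seed are dropped with a
    warning.
    """
    cell_mask = np.asarray(cell_mask, dtype=bool)
    nucleus_labels = np.asarray(nucleus_labels)
    comp = cc_label(cell_mask)
    seeded = np.unique(comp[(nucleus_labels > 0) & cell_mask])
    unseeded = set(np.unique(comp)) - set(seeded) - {0}
    if unseeded:
        warnings.warn(f"{len(unseeded)} cell region(s) without a nucleus "
                      "seed dropped", stacklevel=2)
    keep = np.isin(comp, list(seeded)) & cell_mask
    dist = ndimage.distance_transform_edt(keep)
    return watershed(-dist, markers=nucleus_labels * keep, mask=keep)


def segment_cells(
    green_stack: np.ndarray,
    red_stack: np.ndarray,
    n_frames: int = 5,
    pixel_size_nm: float = 93.0,
) -> CellMap:
    """Full segmentation stage: 5-frame averages, thresholds, watershed.

    The green (cell body) and red (nuclear marker) channels are averaged
    over ``n_frames`` consecutive images, thresholded independently, and
    the labelled nucleus masks seed the watershed that splits joined cells.
    """
    g_avg = frame_average(np.asarray(green_stack, dtype=float), n_frames)
    r_avg = frame_average(np.asarray(red_stack, dtype=float), n_frames)
    cell_mask = threshold_masks(g_avg, pixel_size_nm=pixel_size_nm)
    nuc_mask = threshold_masks(r_avg, pixel_size_nm=pixel_size_nm,
                               min_area_px=int(0.25 * 1e6 / pixel_size_nm**2))
    nucleus_labels = cc_label(nuc_mask).astype(np.int32)
    cell_labels = watershed_split(cell_mask, nucleus_labels).astype(np.int32)
    return CellMap(cell_labels=cell_labels, nucleus_labels=nucleus_labels,
                   pixel_size_nm=pixel_size_nm)


def assign_tracks(track_summary: pd.DataFrame,
                  cellmap: CellMap) -> pd.DataFrame:
    """Annotate a track summary with cell id and compartment.

    Assignment uses each track's lateral centroid pixel: nucleus if it falls
    in a nucleus label, else cytoplasm if inside a cell label, else outside.
    z is ignored because the masks are 2D.
    """
    px = cellmap.pixel_size_nm
    h, w = cellmap.cell_labels.shape
    cell_ids, compartments = [], []
    for _, row in track_summary.iterrows():
        col = int(row["centroid_x_nm"] / px)
        r = int(row["centroid_y_nm"] / px)
        if not (0 <= r < h and 0 <= col < w):
            cell_ids.append(0)
            compartments.append("outside")
            continue
        nuc = int(cellmap.nucleus_labels[r, col])
        cell = int(cellmap.cell_labels[r, col])
        if nuc > 0:
            cell_ids.append(cellmap.parent.get(nuc, cell))
            compartments.append("nucleus")
        elif cell > 0:
            cell_ids.append(cell)
            compartments.append("cytoplasm")
        else:
            cell_ids.append(0)
            compartments.append("outside")
    out = track_summary.copy()
    out["cell_id"] = cell_ids
    out["compartment"] = compartments
    return out
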