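"""Nucleus detection and per-cell intensity measurement.

The detection chain approximates intensity-based nuclear segmentation as used
in interactive histology tools: Gaussian smoothing (``sigma``), local
background removal by morphological opening (``background_radius``), a global
``threshold``, hole filling, watershed splitting of touching objects on the
distance transform, and an area filter. The parameter names (sigma,
background radius, threshold) are the ones practitioners tune.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.morphology import disk, opening
from skimage.segmentation import expand_labels, watershed

from .image import SectionImage

CELL_CSV_BASE_COLUMNS = ["cell_id", "x", "y", "area_px"]


@dataclass
class CellTable:
    """Detected cells: a per-cell table plus the nucleus label raster that
    produced it (needed to reconstruct masks for intensity measurement).

    ``df`` columns grow as the pipeline runs: ``cell_id, x, y, area_px``
    after detection; ``<channel>_nuclear`` / ``<channel>_whole_cell`` /
    ``<channel>_corrected`` after measurement and background subtraction;
    ``region_id`` / ``unassigned`` after atlas mapping; ``class`` after
    classification; plus any boolean marker flags.
    """

    df: pd.DataFrame
    labels: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.df)

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "CellTable":
        return cls(df=pd.read_csv(path))


def detect_nuclei(
    section: SectionImage,
    channel: str = "nuclear",
    sigma: float = 1.5,
    background_radius: float = 8.0,
    threshold: float = 30.0,
    min_area: int = 10,
    max_area: int = 400,
    peak_min_distance: int = 3,
) -> CellTable:
    """Detect nuclei in one channel and return one record per object.

    Pipeline: Gaussian smooth → subtract local background (grey opening with
    a disc of ``background_radius``; skipped when 0) → binarize at
    ``threshold`` → fill holes → split touching objects by watershed on the
    distance transform → keep components with area in [min_area, max_area].
    An all-background image yields an empty table, not an error.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if min_area > max_area:
        raise ValueError("min_area must not exceed max_area")
    img = section.channel(channel)
    smoothed = ndi.gaussian_filter(img, sigma) if sigma > 0 else img.astype(float)
    if background_radius > 0:
        bg = opening(smoothed, disk(int(round(background_radius))))
        work = np.clip(smoothed - bg, 0.0, None)
    else:
        work = smoothed
    binary = work > threshold
    if not binary.any():
        return CellTable(
            df=pd.DataFrame(columns=CELL_CSV_BASE_COLUMNS),
            labels=np.zeros(img.shape, dtype=np.int32),
            meta=_detection_meta(channel, sigma, background_radius, threshold,
                                 min_area, max_area),
        )
    binary = ndi.binary_fill_holes(binary)
    components, _ = ndi.label(binary)
    # markers at intensity maxima of the processed image, watershed flooding
    # on the inverted intensity surface: touching nuclei of similar size form
    # a flat distance-transform ridge with a single maximum, whereas the
    # intensity profile keeps one peak and one basin per nucleus
    peaks = peak_local_max(
        work,
        min_distance=peak_min_distance,
        labels=components,
        exclude_border=False,
    )
    markers = np.zeros_like(components)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    # components without a recorded peak (flat plateaus) keep one marker
    have = np.unique(components[markers > 0])
    for comp in np.unique(components):
        if comp == 0 or comp in have:
            continue
        rr, cc = np.nonzero(components == comp)
        k = int(np.argmax(work[rr, cc]))
        markers[rr[k], cc[k]] = markers.max() + 1
    split = watershed(-work, markers, mask=binary)
    # area filter + deterministic relabeling in (row, col) order of centroids
    ids, counts = np.unique(split[split > 0], return_counts=True)
    keep = ids[(counts >= min_area) & (counts <= max_area)]
    labels = np.where(np.isin(split, keep), split, 0)
    records = []
    # intensity-weighted centroids: robust to mask asymmetry when touching
    # nuclei are split, where binary centroids drift off the true center
    centroids = ndi.center_of_mass(work, labels, keep) if len(keep) else []
    areas = ndi.sum_labels(np.ones_like(labels), labels, keep) if len(keep) else []
    order = sorted(
        range(len(keep)), key=lambda i: (centroids[i][0], centroids[i][1])
    )
    relabeled = np.zeros_like(labels, dtype=np.int32)
    for new_id, i in enumerate(order, start=1):
        relabeled[labels == keep[i]] = new_id
        cy, cx = centroids[i]
        records.append(
            {
                "cell_id": new_id,
                "x": float(cx),
                "y": float(cy),
                "area_px": int(areas[i]),
            }
        )
    df = pd.DataFrame(records, columns=CELL_CSV_BASE_COLUMNS)
    return CellTable(
        df=df,
        labels=relabeled,
        meta=_detection_meta(channel, sigma, background_radius, threshold,
                             min_area, max_area),
    )


def _detection_meta(channel, sigma, background_radius, threshold, min_area, max_area):
    return {
        "detection": {
            "channel": channel,
            "sigma": sigma,
            "background_radius": background_radius,
            "threshold": threshold,
            "min_area": min_area,
            "max_area": max_area,
        }
    }


def measure_intensity(
    cells: CellTable,
    section: SectionImage,
    channel: str,
    compartment: str = "nuclear",
    ring_width: float = 2.0,
) -> CellTable:
    """Mean channel intensity per cell over the nuclear mask
    (``compartment="nuclear"``) or the nucleus dilated by ``ring_width``
    pixels (``"whole_cell"``), with contested pixels between touching cells
    assigned to the nearest nucleus.

    ``ring_width=0`` makes whole-cell identical to nuclear. Sets the column
    ``<channel>_<compartment>``.
    """
    if compartment not in ("nuclear", "whole_cell"):
        raise ValueError("compartment must be 'nuclear' or 'whole_cell'")
    if ring_width < 0:
        raise ValueError("ring_width must be >= 0")
    if cells.labels is None:
        raise ValueError("cells carry no label raster; rerun detection")
    img = section.channel(channel)
    ids = cells.df["cell_id"].to_numpy()
    col = f"{channel}_{compartment}"
    if len(ids) == 0:
        cells.df[col] = pd.Series(dtype=float)
        return cells
    if compartment == "nuclear" or ring_width == 0:
        masks = cells.labels
    else:
        # nearest-nucleus (generalized Voronoi) partition of the dilation ring
        masks = expand_labels(cells.labels, distance=ring_width)
    means = ndi.mean(img, labels=masks, index=ids)
    cells.df[col] = np.asarray(means, dtype=float)
    return cells


def auto_background_rois(
    cells: CellTable,
    shape: tuple[int, int],
    n: int = 3,
    size: int = 20,
    margin: int = 2,
) -> list[tuple[int, int, int, int]]:
    """Pick ``n`` signal-negative rectangular ROIs (``size``×``size``) that
    contain no detected cell pixels, scanning a deterministic grid.

    Mirrors the manual practice of circling a few cell-free patches to
    estimate background. On densely populated sections the window shrinks
    (halving down to 4 px) until enough clear patches exist; raises if even
    4-px windows cannot be found.
    """
    if cells.labels is None:
        raise ValueError("cells carry no label raster")
    rows, cols = shape
    occupied = ndi.binary_dilation(cells.labels > 0, iterations=margin)
    while size >= 4:
        rois: list[tuple[int, int, int, int]] = []
        step = size + 2 * margin
        for r0 in range(margin, rows - size - margin, step):
            for c0 in range(margin, cols - size - margin, step):
                if not occupied[r0 : r0 + size, c0 : c0 + size].any():
                    rois.append((c0, r0, c0 + size, r0 + size))
                    if len(rois) == n:
                        return rois
        size //= 2
    raise RuntimeError(f"found only {len(rois)} cell-free ROIs, wanted {n}")


def subtract_background(
    cells: CellTable,
    section: SectionImage,
    channel: str,
    background_rois: list[tuple[float, float, float, float]],
    compartment: str = "nuclear",
) -> CellTable:
    """Background-correct per-cell intensities: the mean intensities of the
    given signal-negative ROIs (rectangles ``(x0, y0, x1, y1)``) are averaged
    and subtracted from each cell's measured mean; results clamp at 0.

    Sets ``<channel>_corrected`` and records the correction value in
    ``cells.meta``. Warns (but proceeds) if an ROI overlaps detected cells.
    """
    if not background_rois:
        raise ValueError("at least one background ROI is required")
    img = section.channel(channel)
    rows, cols = img.shape
    roi_means = []
    for x0, y0, x1, y1 in background_rois:
        c0, c1 = sorted((int(round(x0)), int(round(x1))))
        r0, r1 = sorted((int(round(y0)), int(round(y1))))
        if c0 < 0 or r0 < 0 or c1 > cols or r1 > rows or c1 <= c0 or r1 <= r0:
            raise ValueError(f"ROI ({x0},{y0},{x1},{y1}) outside image or empty")
        if cells.labels is not None and (cells.labels[r0:r1, c0:c1] > 0).any():
            import warnings

            warnings.warn(
                f"background ROI ({x0},{y0},{x1},{y1}) contains detected cell "
                "pixels; correction may be biased",
                stacklevel=2,
            )
        roi_means.append(float(img[r0:r1, c0:c1].mean()))
    correction = float(np.mean(roi_means))
    source_col = f"{channel}_{compartment}"
    if source_col not in cells.df.columns:
        raise ValueError(f"intensity column {source_col!r} missing; measure first")
    cells.df[f"{channel}_corrected"] = np.clip(
        cells.df[source_col].to_numpy(dtype=float) - correction, 0.0, None
    )
    cells.meta.setdefault("background_correction", {})[channel] = {
        "roi_means": roi_means,
        "correction": correction,
        "compartment": compartment,
        "clamped_at_zero": True,
    }
    return cells
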