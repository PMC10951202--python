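"""Anatomical heatmaps: paint a per-region statistic onto the atlas raster."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from matplotlib import colormaps
from matplotlib.colors import Normalize

from .atlas import AtlasPlate

ABSENT_GREY = (128, 128, 128)
BACKGROUND_WHITE = (255, 255, 255)


def render_region_heatmap(
    stats: pd.DataFrame,
    atlas: AtlasPlate,
    statistic: str = "prev_high",
    cmap: str = "viridis",
    vmin: float | None = None,
    vmax: float | None = None,
) -> tuple[np.ndarray, dict]:
    """Fill each region's pixels with the colormap value of its statistic.

    Regions whose statistic is absent (NaN or missing from the table) are
    drawn neutral grey, distinguishable from the colormap minimum; pixels
    outside the atlas stay white. Returns (RGB uint8 raster, colorbar
    metadata: colormap name, vmin, vmax, absent color).
    """
    if statistic not in stats.columns:
        raise ValueError(f"unknown statistic field {statistic!r}")
    values = {
        int(r): float(v)
        for r, v in zip(stats["region_id"], stats[statistic])
        if r != 0
    }
    finite = [v for v in values.values() if np.isfinite(v)]
    if not finite:
        raise ValueError(f"statistic {statistic!r} absent for every region")
    lo = float(min(finite)) if vmin is None else float(vmin)
    hi = float(max(finite)) if vmax is None else float(vmax)
    if hi == lo:
        hi = lo + 1.0
    norm = Normalize(vmin=lo, vmax=hi)
    mapper = colormaps[cmap]
    rgb = np.empty((*atlas.labels.shape, 3), dtype=np.uint8)
    rgb[...] = BACKGROUND_WHITE
    for rid in np.unique(atlas.labels):
        if rid == 0:
            continue
        mask = atlas.labels == rid
        v = values.get(int(rid), np.nan)
        if not np.isfinite(v):
            rgb[mask] = ABSENT_GREY
        else:
            color = np.asarray(mapper(norm(v))[:3]) * 255
            rgb[mask] = color.round().astype(np.uint8)
    meta = {
        "statistic": statistic,
        "colormap": cmap,
        "vmin": lo,
        "vmax": hi,
        "absent_color_rgb": list(ABSENT_GREY),
        "background_rgb": list(BACKGROUND_WHITE),
    }
    return rgb, meta


def save_heatmap(
    rgb: np.ndarray, meta: dict, path: str | Path
) -> None:
    """Write the heatmap as PNG with a JSON colorbar sidecar."""
    import imageio.v3 as iio

    path = Path(path)
    iio.imwrite(path, rgb)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))
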