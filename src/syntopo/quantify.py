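"""Regional aggregation of classified, atlas-assigned cells.

Produces the per-region statistics the topography analysis reports: class
prevalence percentages, relative chromogenic density, colocalization
fractions, and intensity-per-volume. Regions with no cells report *absent*
statistics (NaN), never 0% — "no data" and "zero prevalence" are different
claims — and are excluded from downstream correlations.
"""

from __future__ import annotations

from typing import Callable

import numpy as np
import pandas as pd

from .atlas import RegionOntology, aggregate_to_parent
from .classify import CLASS_NAMES
from .detect import CellTable

REGION_STATS_COLUMNS = [
    "region_id",
    "acronym",
    "n_low",
    "n_med",
    "n_high",
    "n_total",
    "prev_low",
    "prev_med",
    "prev_high",
]


def region_class_prevalence(
    cells,
    ontology: RegionOntology,
    level: int | None = None,
    include_empty: bool = False,
) -> pd.DataFrame:
    """Per-region class counts and prevalence percentages.

    ``prev_<class> = 100 · n_<class> / n_total``. Cells must carry
    ``region_id`` and ``class``. Counts are first aggregated up the ontology
    to ``level`` (depth; None = leaf level, i.e. no aggregation). Region 0 is
    reported as a separate "unassigned" row. With ``include_empty``, ontology
    regions at the requested level with no cells appear with zero counts and
    NaN prevalences.
    """
    df = cells.df if isinstance(cells, CellTable) else cells
    if "class" not in df.columns or df["class"].isna().any():
        raise ValueError("cells lack class labels; classify first")
    if "region_id" not in df.columns:
        raise ValueError("cells lack region_id; map to atlas first")
    counts = (
        df.assign(n=1)
        .pivot_table(
            index="region_id", columns="class", values="n", aggfunc="sum", fill_value=0
        )
        .reindex(columns=list(CLASS_NAMES), fill_value=0)
        .reset_index()
    )
    counts.columns = ["region_id", "n_low", "n_med", "n_high"]
    if level is not None:
        counts = aggregate_to_parent(
            counts, ontology, level, value_columns=["n_low", "n_med", "n_high"]
        )
    if include_empty:
        if level is None:
            wanted = [
                r for r in ontology.region_ids if not ontology.children(r)
            ]
        else:
            wanted = sorted(
                {
                    ontology.ancestor_at_depth(r, level)
                    for r in ontology.region_ids
                    if ontology.depth(r) >= level
                }
            )
        missing = [r for r in wanted if r not in set(counts["region_id"])]
        if missing:
            counts = pd.concat(
                [
                    counts,
                    pd.DataFrame(
                        {
                            "region_id": missing,
                            "n_low": 0,
                            "n_med": 0,
                            "n_high": 0,
                        }
                    ),
                ],
                ignore_index=True,
            )
    counts["n_total"] = counts[["n_low", "n_med", "n_high"]].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        for cls, col in zip(("low", "med", "high"), ("n_low", "n_med", "n_high")):
            counts[f"prev_{cls}"] = np.where(
                counts["n_total"] > 0,
                100.0 * counts[col] / counts["n_total"],
                np.nan,
            )
    counts["acronym"] = [
        "unassigned" if r == 0 else ontology.acronym(int(r))
        for r in counts["region_id"]
    ]
    return (
        counts[REGION_STATS_COLUMNS]
        .sort_values("region_id")
        .reset_index(drop=True)
    )


def relative_density(n_positive: int, n_hematoxylin: int) -> float:
    """Relative immunopositive cell density: ``100 · n_positive /
    n_hematoxylin`` (may exceed 100). Undefined for a zero counterstain
    count."""
    if n_hematoxylin == 0:
        raise ZeroDivisionError(
            "relative density undefined: no hematoxylin-positive cells"
        )
    if n_positive < 0 or n_hematoxylin < 0:
        raise ValueError("counts must be nonnegative")
    return 100.0 * n_positive / n_hematoxylin


def colocalization_fraction(
    cells,
    marker_flag: str,
    signal_rule: str | Callable[[pd.DataFrame], np.ndarray] = "medium_or_high",
    intensity_column: str | None = None,
    cutoff: float | None = None,
) -> tuple[float | None, int]:
    """Percent of marker-positive cells that are signal-positive.

    ``signal_rule`` is one of ``"medium_or_high"`` (default: class ∈
    {medium, high}), ``"high"``, ``"intensity_above"`` (requires
    ``intensity_column`` and ``cutoff``), or a callable returning a boolean
    mask. Returns ``(percent, n_marker)``; percent is None when there are no
    marker-positive cells.
    """
    df = cells.df if isinstance(cells, CellTable) else cells
    if marker_flag not in df.columns:
        raise ValueError(f"unknown marker flag {marker_flag!r}")
    marker = df[marker_flag].astype(bool).to_numpy()
    n_marker = int(marker.sum())
    if n_marker == 0:
        return None, 0
    if callable(signal_rule):
        signal = np.asarray(signal_rule(df), dtype=bool)
    elif signal_rule == "medium_or_high":
        signal = df["class"].isin(["medium", "high"]).to_numpy()
    elif signal_rule == "high":
        signal = (df["class"] == "high").to_numpy()
    elif signal_rule == "intensity_above":
        if intensity_column is None or cutoff is None:
            raise ValueError("intensity_above rule needs intensity_column and cutoff")
        signal = (df[intensity_column].to_numpy(dtype=float) > cutoff)
    else:
        raise ValueError(f"unknown signal rule {signal_rule!r}")
    return 100.0 * float((marker & signal).sum()) / n_marker, n_marker


def regional_intensity_density(sum_intensity: float, region_size: float) -> float:
    """Total fluorescence intensity divided by the region's voxel (or pixel)
    count — the intensity-per-volume statistic for cleared whole-organ data."""
    if region_size <= 0:
        raise ZeroDivisionError("region size must be positive")
    if sum_intensity < 0:
        raise ValueError("sum_intensity must be nonnegative")
    return float(sum_intensity) / float(region_size)
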