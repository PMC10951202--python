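"""Anatomical atlas model: a region hierarchy plus the 2D label raster it indexes.

The ontology mirrors the Allen structure-graph layout at toy scale: each node
has an integer ``region_id``, a short ``acronym``, a full ``name`` and a
``parent_id`` (``None`` for roots). Label 0 in a raster is reserved for
"outside atlas"; cells landing there are kept but flagged unassigned rather
than dropped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


class OntologyError(ValueError):
    """Raised when a region table violates the hierarchy invariants."""


@dataclass(frozen=True)
class RegionNode:
    region_id: int
    acronym: str
    name: str
    parent_id: int | None = None


class RegionOntology:
    """A validated forest of brain regions.

    Parameters
    ----------
    nodes
        Region records. ``region_id`` values must be unique and nonzero;
        every non-null ``parent_id`` must itself be a node; parent links
        must be acyclic.
    """

    def __init__(self, nodes: Iterable[RegionNode]):
        self._nodes: dict[int, RegionNode] = {}
        for node in nodes:
            if node.region_id == 0:
                raise OntologyError("region_id 0 is reserved for 'outside atlas'")
            if node.region_id in self._nodes:
                raise OntologyError(f"duplicate region_id {node.region_id}")
            self._nodes[node.region_id] = node
        self._children: dict[int, list[int]] = {rid: [] for rid in self._nodes}
        for node in self._nodes.values():
            if node.parent_id is not None:
                if node.parent_id not in self._nodes:
                    raise OntologyError(
                        f"dangling parent: region {node.region_id} points to "
                        f"missing parent_id {node.parent_id}"
                    )
                self._children[node.parent_id].append(node.region_id)
        self._depth = self._compute_depths()

    def _compute_depths(self) -> dict[int, int]:
        depth: dict[int, int] = {}
        for rid in self._nodes:
            seen: list[int] = []
            cur: int | None = rid
            while cur is not None and cur not in depth:
                if cur in seen:
                    raise OntologyError(f"cycle detected through region_id {cur}")
                seen.append(cur)
                cur = self._nodes[cur].parent_id
            base = -1 if cur is None else depth[cur]
            for i, r in enumerate(reversed(seen)):
                depth[r] = base + 1 + i
        return depth

    # -- basic accessors ---------------------------------------------------

    def __len__(self) -> int:
        return len(self._nodes)

    def __contains__(self, region_id: int) -> bool:
        return region_id in self._nodes

    def __getitem__(self, region_id: int) -> RegionNode:
        return self._nodes[region_id]

    @property
    def region_ids(self) -> list[int]:
        return sorted(self._nodes)

    @property
    def roots(self) -> list[int]:
        return sorted(r for r, n in self._nodes.items() if n.parent_id is None)

    def children(self, region_id: int) -> list[int]:
        return sorted(self._children[region_id])

    def depth(self, region_id: int) -> int:
        """0 for roots, parent depth + 1 otherwise."""
        return self._depth[region_id]

    @property
    def max_depth(self) -> int:
        return max(self._depth.values())

    def descendants(self, region_id: int, include_self: bool = False) -> list[int]:
        if region_id not in self._nodes:
            raise OntologyError(f"unknown region_id {region_id}")
        out: list[int] = [region_id] if include_self else []
        stack = list(self._children[region_id])
        while stack:
            rid = stack.pop()
            out.append(rid)
            stack.extend(self._children[rid])
        return sorted(out)

    def ancestor_at_depth(self, region_id: int, level: int) -> int:
        """The ancestor of ``region_id`` at the given depth (itself if already
        at or above that depth)."""
        if region_id not in self._nodes:
            raise OntologyError(f"unknown region_id {region_id}")
        cur = region_id
        while self._depth[cur] > level:
            parent = self._nodes[cur].parent_id
            assert parent is not None  # depth > 0 implies a parent
            cur = parent
        return cur

    def acronym(self, region_id: int) -> str:
        return self._nodes[region_id].acronym if region_id in self._nodes else ""

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "id": n.region_id,
                "acronym": n.acronym,
                "name": n.name,
                "parent_id": n.parent_id,
            }
            for n in sorted(self._nodes.values(), key=lambda n: n.region_id)
        ]
        return pd.DataFrame(rows, columns=["id", "acronym", "name", "parent_id"])

    def save(self, path: str | Path) -> None:
        path = Path(path)
        df = self.to_frame()
        if path.suffix.lower() == ".json":
            records = df.to_dict(orient="records")
            for rec in records:
                if pd.isna(rec["parent_id"]):
                    rec["parent_id"] = None
                else:
                    rec["parent_id"] = int(rec["parent_id"])
            path.write_text(json.dumps(records, indent=1))
        else:
            df.to_csv(path, index=False)


def load_ontology(path: str | Path) -> RegionOntology:
    """Read a region ontology from CSV (header ``id,acronym,name,parent_id``)
    or a JSON array of objects with the same keys.

    An empty/null ``parent_id`` marks a root. Raises :class:`OntologyError`
    on duplicate ids, dangling parents or cycles.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        records = json.loads(path.read_text())
        if not isinstance(records, list):
            raise OntologyError("JSON ontology must be an array of objects")
    else:
        df = pd.read_csv(path)
        missing = {"id", "acronym", "name", "parent_id"} - set(df.columns)
        if missing:
            raise OntologyError(f"ontology CSV missing columns: {sorted(missing)}")
        records = df.to_dict(orient="records")
    nodes = []
    for rec in records:
        parent = rec.get("parent_id")
        if parent is None or (isinstance(parent, str) and parent.strip() == "") or (
            isinstance(parent, float) and np.isnan(parent)
        ):
            parent = None
        else:
            parent = int(parent)
        nodes.append(
            RegionNode(
                region_id=int(rec["id"]),
                acronym=str(rec["acronym"]),
                name=str(rec["name"]),
                parent_id=parent,
            )
        )
    return RegionOntology(nodes)


@dataclass
class AtlasPlate:
    """A 2D coronal-plate stand-in: integer label raster + its ontology.

    Raster pixels hold region ids (0 = outside atlas). Rasters are indexed
    (row, column), 0-based; a point (x, y) means x = column, y = row, with
    pixel centers at integer coordinates.
    """

    labels: np.ndarray
    ontology: RegionOntology
    pixel_size_um: float = 1.0
    plate_id: str = "plate"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2 or min(self.labels.shape) < 1:
            raise ValueError("labels must be a 2D raster with positive dimensions")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer raster")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        present = np.unique(self.labels)
        unknown = [int(v) for v in present if v != 0 and v not in self.ontology]
        if unknown:
            raise ValueError(f"raster labels not in ontology: {unknown}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def label_at(self, x: float, y: float) -> int:
        """Region id at the nearest pixel to (x, y); 0 outside the plate."""
        row = int(round(y))
        col = int(round(x))
        if 0 <= row < self.labels.shape[0] and 0 <= col < self.labels.shape[1]:
            return int(self.labels[row, col])
        return 0


def region_mask(
    atlas: AtlasPlate, region_id: int, include_descendants: bool = False
) -> np.ndarray:
    """Boolean raster, true where the label equals ``region_id`` (or, when
    ``include_descendants``, any of its descendant ids)."""
    if region_id not in atlas.ontology:
        raise OntologyError(f"unknown region_id {region_id}")
    if include_descendants:
        ids = atlas.ontology.descendants(region_id, include_self=True)
        return np.isin(atlas.labels, ids)
    return atlas.labels == region_id


def aggregate_to_parent(
    stats: pd.DataFrame,
    ontology: RegionOntology,
    level: int,
    value_columns: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Roll per-region values up the hierarchy to the requested depth.

    Each region deeper than ``level`` is re-attributed to its ancestor at
    that depth; numeric columns are summed. Region 0 ("unassigned") passes
    through untouched. Totals are conserved by construction.
    """
    if "region_id" not in stats.columns:
        raise ValueError("stats table must have a 'region_id' column")
    unknown = [
        int(r)
        for r in stats["region_id"].unique()
        if r != 0 and int(r) not in ontology
    ]
    if unknown:
        raise OntologyError(f"stats table references unknown regions: {unknown}")
    if value_columns is None:
        value_columns = [
            c
            for c in stats.columns
            if c != "region_id" and pd.api.types.is_numeric_dtype(stats[c])
        ]
    out = stats.copy()
    out["region_id"] = [
        0 if r == 0 else ontology.ancestor_at_depth(int(r), level)
        for r in out["region_id"]
    ]
    grouped = out.groupby("region_id", as_index=False)[list(value_columns)].sum()
    return grouped.sort_values("region_id").reset_index(drop=True)
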