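"""Synthetic atlases, section images, DAB pairs and misalignments with
exportable ground truth.

Everything downstream — detection, classification, registration,
quantification, concordance — is exercisable against these generators, whose
outputs carry full ground truth (cell placements, true classes and
intensities, per-region class mixtures, the exact misalignment applied).

The intensity model mirrors the statistical structure the mean±SD classifier
assumes: three separable per-cell intensity populations (low / medium / high)
over a noisy background. Defaults (m_low=40, m_med=100, m_high=180,
s_class=10, background=20, s_bg=5 on an 8-bit-like scale) give realistic
misclassification at the class boundaries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import cKDTree

from .atlas import AtlasPlate, RegionNode, RegionOntology
from .image import SectionImage
from .register import DisplacementField, apply_affine

CLASS_NAMES = ("low", "medium", "high")


class PackingError(RuntimeError):
    """Raised when rejection sampling cannot place the requested objects."""


@dataclass(frozen=True)
class ClassMixture:
    """Mixture weights (π_low, π_med, π_high); must sum to 1."""

    low: float
    medium: float
    high: float

    def __post_init__(self) -> None:
        w = self.as_array()
        if (w < 0).any():
            raise ValueError("mixture weights must be nonnegative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(f"mixture weights must sum to 1, got {w.sum()!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.low, self.medium, self.high], dtype=float)


@dataclass
class IntensityModel:
    """Per-class signal intensities and rendering parameters.

    ``m_low < m_med < m_high`` are the class mean intensities (arbitrary
    units), ``s_class`` the within-class SD, ``background``/``s_bg`` the
    background level and noise SD, ``radius_range`` the nucleus radius range
    in pixels. Nuclei are rendered as isotropic Gaussian-profile discs
    truncated at 3 sigma; the signal channel deposits the cell's class
    intensity over a disc slightly larger than the nucleus so nuclear-mask
    means recover it.
    """

    m_low: float = 40.0
    m_med: float = 100.0
    m_high: float = 180.0
    s_class: float = 10.0
    background: float = 20.0
    s_bg: float = 5.0
    radius_range: tuple[float, float] = (2.0, 3.0)
    nuclear_amplitude: float = 160.0

    def __post_init__(self) -> None:
        if not (self.m_low < self.m_med < self.m_high):
            raise ValueError("class means must satisfy m_low < m_med < m_high")
        if self.s_class < 0 or self.s_bg < 0:
            raise ValueError("SDs must be nonnegative")
        if not (0 < self.radius_range[0] <= self.radius_range[1]):
            raise ValueError("radius_range must be positive and ordered")

    @property
    def class_means(self) -> np.ndarray:
        return np.array([self.m_low, self.m_med, self.m_high])


@dataclass
class GroundTruth:
    """Everything a generator knows that the pipeline has to recover."""

    cells: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["x", "y", "region_id", "true_class", "intensity", "radius"]
        )
    )
    mixtures: dict[int, ClassMixture] = field(default_factory=dict)
    transform: "AffineAnchorTransform | None" = None
    dab_positive_count: int | None = None
    hematoxylin_count: int | None = None
    particle_areas: list[int] = field(default_factory=list)

    def save(self, directory: str | Path, stem: str = "truth") -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.cells.to_csv(directory / f"{stem}_cells.csv", index=False)
        meta: dict = {
            "mixtures": {
                str(rid): list(m.as_array()) for rid, m in self.mixtures.items()
            },
            "dab_positive_count": self.dab_positive_count,
            "hematoxylin_count": self.hematoxylin_count,
            "particle_areas": self.particle_areas,
        }
        if self.transform is not None:
            meta["transform"] = self.transform.to_json()
        (directory / f"{stem}_meta.json").write_text(json.dumps(meta, indent=1))


@dataclass
class AffineAnchorTransform:
    """An exact forward point mapping: affine followed by a smooth anchor
    displacement field evaluated in the affine's output frame.

    ``apply(p) = A(p) + D(A(p))`` where ``D`` interpolates the sampled anchor
    displacements. The same object supplies landmark pairs for registration
    tests and an approximate inverse for image resampling.
    """

    affine: np.ndarray
    anchor_nodes: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    anchor_displacements: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    field_scale: float = 128.0
    _field: DisplacementField | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.affine = np.asarray(self.affine, dtype=float)
        self.anchor_nodes = np.asarray(self.anchor_nodes, dtype=float).reshape(-1, 2)
        self.anchor_displacements = np.asarray(
            self.anchor_displacements, dtype=float
        ).reshape(-1, 2)
        if len(self.anchor_nodes) and np.abs(self.anchor_displacements).max() > 0:
            self._field = DisplacementField(
                self.anchor_nodes,
                self.anchor_displacements,
                gaussian_scale=self.field_scale,
            )

    def apply(self, points: np.ndarray) -> np.ndarray:
        out = apply_affine(self.affine, points)
        if self._field is not None:
            out = out + self._field(out)
        return out

    def invert(self, points: np.ndarray, n_iter: int = 4) -> np.ndarray:
        """Approximate inverse by fixed-point iteration on the displacement
        field (exact when there is no nonlinear part)."""
        q = np.atleast_2d(np.asarray(points, dtype=float))
        A = self.affine[:, :2]
        Ainv = np.linalg.inv(A)
        u = q.copy()
        if self._field is not None:
            for _ in range(n_iter):
                u = q - self._field(u)
        return (u - self.affine[:, 2]) @ Ainv.T

    def landmark_pairs(self, atlas_points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(section point, atlas point) pairs generated by the true mapping —
        the input a landmark-based registration needs to undo this transform."""
        atlas_points = np.atleast_2d(np.asarray(atlas_points, dtype=float))
        return self.apply(atlas_points), atlas_points

    def to_json(self) -> dict:
        return {
            "affine": self.affine.tolist(),
            "anchor_nodes": self.anchor_nodes.tolist(),
            "anchor_displacements": self.anchor_displacements.tolist(),
            "field_scale": self.field_scale,
        }

    @classmethod
    def from_json(cls, data: dict) -> "AffineAnchorTransform":
        return cls(
            affine=np.asarray(data["affine"], dtype=float),
            anchor_nodes=np.asarray(data["anchor_nodes"], dtype=float),
            anchor_displacements=np.asarray(data["anchor_displacements"], dtype=float),
            field_scale=float(data.get("field_scale", 128.0)),
        )


# ---------------------------------------------------------------------------
# toy atlas


def make_toy_atlas(
    n_regions: int,
    shape: tuple[int, int] = (512, 512),
    seed: int = 0,
    pixel_size_um: float = 1.0,
    balance_iterations: int = 80,
) -> tuple[AtlasPlate, RegionOntology]:
    """Generate a plate of ``n_regions`` contiguous territories labeled 1..n,
    under a single root node.

    Territories are cells of a capacity-balanced power diagram (a weighted
    Voronoi tessellation whose weights are adapted until region areas are
    near-equal, with Lloyd centroid updates for compactness). Power cells are
    convex, so every region is contiguous; near-equal areas make a fixed
    per-region cell budget feasible everywhere. Deterministic for a fixed
    seed; every region owns at least one pixel.
    """
    rows, cols = int(shape[0]), int(shape[1])
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    if rows < 1 or cols < 1:
        raise ValueError("shape must be positive")
    if n_regions > rows * cols:
        raise ValueError("n_regions exceeds pixel count")
    rng = np.random.default_rng(seed)
    flat = rng.choice(rows * cols, size=n_regions, replace=False)
    seeds = np.column_stack([flat // cols, flat % cols]).astype(float)
    # balance on a coarsened grid (block centers), assign at full resolution
    coarse = max(1, min(rows, cols) // 256)
    crr = np.arange(rows // coarse) * coarse + (coarse - 1) / 2.0
    ccc = np.arange(cols // coarse) * coarse + (coarse - 1) / 2.0
    cgrid = np.array([[y, x] for y in crr for x in ccc])
    weights = np.zeros(n_regions)
    target = len(cgrid) / n_regions
    for it in range(max(1, balance_iterations)):
        # argmin_i |p - s_i|^2 - w_i  ==  argmin_i -2 p.s_i + (|s_i|^2 - w_i)
        scores = -2.0 * cgrid @ seeds.T + ((seeds**2).sum(axis=1) - weights)
        lab = np.argmin(scores, axis=1)
        areas = np.bincount(lab, minlength=n_regions)
        if it % 2 == 0 and it < balance_iterations // 2:
            ys = np.bincount(lab, weights=cgrid[:, 0], minlength=n_regions)
            xs = np.bincount(lab, weights=cgrid[:, 1], minlength=n_regions)
            nz = areas > 0
            seeds[nz, 0] = ys[nz] / areas[nz]
            seeds[nz, 1] = xs[nz] / areas[nz]
        weights += 0.3 * (target - areas) / target * (target * coarse**2 / np.pi)
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    grid = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    scores = -2.0 * grid @ seeds.T + ((seeds**2).sum(axis=1) - weights)
    lab = np.argmin(scores, axis=1)
    labels = (lab.reshape(rows, cols) + 1).astype(np.int32)
    if len(np.unique(labels)) < n_regions:  # pragma: no cover - degenerate seeds
        raise RuntimeError("area balancing produced an empty region")
    root_id = n_regions + 1
    nodes = [RegionNode(root_id, "root", "whole plate", None)]
    nodes += [
        RegionNode(i, f"R{i}", f"region {i}", root_id) for i in range(1, n_regions + 1)
    ]
    ontology = RegionOntology(nodes)
    plate = AtlasPlate(
        labels=labels,
        ontology=ontology,
        pixel_size_um=pixel_size_um,
        plate_id=f"toy-{n_regions}-{seed}",
    )
    return plate, ontology


def random_mixtures(
    region_ids,
    seed: int = 0,
    alpha: tuple[float, float, float] = (2.0, 6.0, 2.0),
) -> dict[int, ClassMixture]:
    """Independent Dirichlet class mixtures, one per region.

    The default concentration (2, 6, 2) makes medium the majority class
    (mean weights 0.2/0.6/0.2) with substantial regional variation — the
    configuration a mean±SD tail classifier is built for, since low and high
    are by construction the tails of the dataset-wide intensity
    distribution.
    """
    rng = np.random.default_rng(seed)
    out: dict[int, ClassMixture] = {}
    for rid in region_ids:
        w = rng.dirichlet(alpha)
        w = w / w.sum()
        out[int(rid)] = ClassMixture(*w)
    return out


# ---------------------------------------------------------------------------
# IF section rendering


class _SeparationGrid:
    """Uniform hash grid for min-separation rejection sampling."""

    def __init__(self, min_sep: float):
        self.min_sep = float(min_sep)
        self.cell = max(self.min_sep, 1e-6)
        self.buckets: dict[tuple[int, int], list[tuple[float, float]]] = {}

    def ok(self, x: float, y: float) -> bool:
        if self.min_sep <= 0:
            return True
        bx, by = int(x // self.cell), int(y // self.cell)
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for px, py in self.buckets.get((bx + dx, by + dy), ()):
                    if (px - x) ** 2 + (py - y) ** 2 < self.min_sep**2:
                        return False
        return True

    def add(self, x: float, y: float) -> None:
        self.buckets.setdefault((int(x // self.cell), int(y // self.cell)), []).append(
            (x, y)
        )


def _stamp_cells(
    shape: tuple[int, int], cells: pd.DataFrame, amplitude: float
) -> tuple[np.ndarray, np.ndarray]:
    """Render the nuclear (additive Gaussian blobs) and signal (max of flat
    discs at each cell's intensity) foregrounds."""
    nuclear = np.zeros(shape, dtype=float)
    signal = np.zeros(shape, dtype=float)
    rows, cols = shape
    for x, y, intensity, radius in zip(
        cells["x"], cells["y"], cells["intensity"], cells["radius"]
    ):
        sig_r = 1.6 * radius
        ext = max(1.8 * radius, sig_r)
        r0 = max(int(np.floor(y - ext)), 0)
        r1 = min(int(np.ceil(y + ext)) + 1, rows)
        c0 = max(int(np.floor(x - ext)), 0)
        c1 = min(int(np.ceil(x + ext)) + 1, cols)
        yy, xx = np.mgrid[r0:r1, c0:c1]
        d2 = (yy - y) ** 2 + (xx - x) ** 2
        sigma = 0.6 * radius
        blob = amplitude * np.exp(-d2 / (2.0 * sigma**2))
        blob[d2 > (3 * sigma) ** 2] = 0.0
        nuclear[r0:r1, c0:c1] += blob
        patch = signal[r0:r1, c0:c1]
        disc = d2 <= sig_r**2
        patch[disc] = np.maximum(patch[disc], intensity)
    return nuclear, signal


def render_if_section(
    atlas: AtlasPlate,
    mixtures: dict[int, ClassMixture],
    cells_per_region: int,
    model: IntensityModel | None = None,
    seed: int = 0,
    min_separation: float | None = None,
    modality: str = "IF",
    max_retries: int = 1000,
) -> tuple[SectionImage, GroundTruth]:
    """Render a two-channel ("nuclear", "signal") section over an atlas plate.

    Per region, ``cells_per_region`` nuclei are placed uniformly inside the
    region's territory with minimum separation (default 2× the max nucleus
    radius) enforced globally by rejection sampling; exceeding the per-cell
    retry cap raises :class:`PackingError` naming the region. Each cell's
    class is drawn from the region's mixture and its signal intensity from
    N(m_class, s_class), clipped at 0.
    """
    if model is None:
        model = IntensityModel()
    if cells_per_region < 0:
        raise ValueError("cells_per_region must be >= 0")
    rng = np.random.default_rng(seed)
    labels = atlas.labels
    region_ids = [int(r) for r in np.unique(labels) if r != 0]
    missing = [r for r in region_ids if r not in mixtures]
    if missing:
        raise ValueError(f"no mixture given for regions {missing}")
    if min_separation is None:
        min_separation = 2.0 * model.radius_range[1]
    grid = _SeparationGrid(min_separation)
    rows, cols = labels.shape
    records: list[dict] = []
    means = model.class_means
    for rid in region_ids:
        rr, cc = np.nonzero(labels == rid)
        if len(rr) == 0:
            continue
        weights = mixtures[rid].as_array()
        for _ in range(cells_per_region):
            for _attempt in range(max_retries):
                k = rng.integers(len(rr))
                y = float(np.clip(rr[k] + rng.uniform(-0.5, 0.5), 0.0, rows - 1.0))
                x = float(np.clip(cc[k] + rng.uniform(-0.5, 0.5), 0.0, cols - 1.0))
                if grid.ok(x, y):
                    break
            else:
                raise PackingError(
                    f"could not place cell in region {rid}: separation "
                    f"{min_separation:.1f} px infeasible after {max_retries} retries"
                )
            grid.add(x, y)
            cls = int(rng.choice(3, p=weights))
            intensity = float(max(rng.normal(means[cls], model.s_class), 0.0))
            radius = float(rng.uniform(*model.radius_range))
            records.append(
                {
                    "x": x,
                    "y": y,
                    "region_id": rid,
                    "true_class": CLASS_NAMES[cls],
                    "intensity": intensity,
                    "radius": radius,
                }
            )
    cells = pd.DataFrame(
        records, columns=["x", "y", "region_id", "true_class", "intensity", "radius"]
    )
    nuclear_fg, signal_fg = _stamp_cells((rows, cols), cells, model.nuclear_amplitude)
    nuclear = model.background + rng.normal(0.0, model.s_bg, (rows, cols)) + nuclear_fg
    signal = model.background + rng.normal(0.0, model.s_bg, (rows, cols)) + signal_fg
    section = SectionImage(
        channels={
            "nuclear": np.clip(nuclear, 0.0, None),
            "signal": np.clip(signal, 0.0, None),
        },
        pixel_size_um=atlas.pixel_size_um,
        modality=modality,
    )
    truth = GroundTruth(cells=cells, mixtures={r: mixtures[r] for r in region_ids})
    return section, truth


# ---------------------------------------------------------------------------
# DAB pair rendering


def _grow_blob(rng: np.random.Generator, area: int) -> np.ndarray:
    """Random 4-connected pixel blob of exactly ``area`` pixels, as (row, col)
    offsets from its seed pixel."""
    blob = {(0, 0)}
    frontier = [(0, 0)]
    while len(blob) < area:
        base = frontier[rng.integers(len(frontier))]
        nbrs = [
            (base[0] + dr, base[1] + dc)
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1))
            if (base[0] + dr, base[1] + dc) not in blob
        ]
        if not nbrs:
            frontier.remove(base)
            continue
        new = nbrs[rng.integers(len(nbrs))]
        blob.add(new)
        frontier.append(new)
    return np.array(sorted(blob))


def render_dab_section(
    n_positive: int,
    n_hematoxylin: int,
    size_range_px: tuple[int, int] = (6, 14),
    shape: tuple[int, int] = (512, 512),
    seed: int = 0,
    max_retries: int = 1000,
) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Render a chromogenic pair: a bright-field raster with exactly
    ``n_positive`` dark immunopositive particles (pixel areas drawn uniformly
    from ``size_range_px``, non-overlapping), and a counterstain raster with
    ``n_hematoxylin`` dark nuclei. Ground truth records both counts and every
    particle's area.
    """
    if n_positive < 0 or n_hematoxylin < 0:
        raise ValueError("counts must be >= 0")
    lo, hi = int(size_range_px[0]), int(size_range_px[1])
    if lo < 1 or hi < lo:
        raise ValueError("size_range_px must be ordered positive integers")
    rng = np.random.default_rng(seed)
    rows, cols = int(shape[0]), int(shape[1])
    field_level, particle_level, nucleus_level = 235.0, 60.0, 95.0
    dab = np.full((rows, cols), field_level)
    occupied = np.zeros((rows, cols), dtype=bool)
    areas: list[int] = []
    for i in range(n_positive):
        area = int(rng.integers(lo, hi + 1))
        offsets = _grow_blob(rng, area)
        for _attempt in range(max_retries):
            r = int(rng.integers(2, rows - 2))
            c = int(rng.integers(2, cols - 2))
            pr, pc = offsets[:, 0] + r, offsets[:, 1] + c
            if (pr < 1).any() or (pr >= rows - 1).any() or (pc < 1).any() or (
                pc >= cols - 1
            ).any():
                continue
            # require a 1-px clear moat so particles never touch (8-conn safe)
            window = occupied[pr.min() - 1 : pr.max() + 2, pc.min() - 1 : pc.max() + 2]
            if not window.any():
                break
        else:
            raise PackingError(f"could not place DAB particle {i}")
        dab[pr, pc] = particle_level
        occupied[pr, pc] = True
        occupied[pr.min() - 1 : pr.max() + 2, pc.min() - 1 : pc.max() + 2] |= True
        areas.append(area)
    hema = np.full((rows, cols), field_level)
    hgrid = _SeparationGrid(7.0)
    for i in range(n_hematoxylin):
        for _attempt in range(max_retries):
            y = rng.uniform(3, rows - 4)
            x = rng.uniform(3, cols - 4)
            if hgrid.ok(x, y):
                break
        else:
            raise PackingError(f"could not place hematoxylin nucleus {i}")
        hgrid.add(x, y)
        radius = rng.uniform(2.0, 3.0)
        r0 = max(int(y - radius) - 1, 0)
        r1 = min(int(y + radius) + 2, rows)
        c0 = max(int(x - radius) - 1, 0)
        c1 = min(int(x + radius) + 2, cols)
        yy, xx = np.mgrid[r0:r1, c0:c1]
        disc = (yy - y) ** 2 + (xx - x) ** 2 <= radius**2
        patch = hema[r0:r1, c0:c1]
        patch[disc] = nucleus_level
    dab += rng.normal(0.0, 3.0, dab.shape)
    hema += rng.normal(0.0, 3.0, hema.shape)
    truth = GroundTruth(
        dab_positive_count=n_positive,
        hematoxylin_count=n_hematoxylin,
        particle_areas=areas,
    )
    return np.clip(dab, 0, 255), np.clip(hema, 0, 255), truth


# ---------------------------------------------------------------------------
# misalignment


def make_transform(
    shape: tuple[int, int],
    rotation_deg: float = 0.0,
    scale: float = 1.0,
    translation: tuple[float, float] = (0.0, 0.0),
    anchor_nodes: np.ndarray | None = None,
    anchor_displacements: np.ndarray | None = None,
) -> AffineAnchorTransform:
    """Deterministic rotation/scale about the image center plus translation,
    optionally composed with an anchor displacement field."""
    if scale <= 0:
        raise ValueError("scale must be positive")
    rows, cols = shape
    cx, cy = (cols - 1) / 2.0, (rows - 1) / 2.0
    th = np.deg2rad(rotation_deg)
    R = scale * np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    t = np.array([cx, cy]) - R @ np.array([cx, cy]) + np.asarray(translation, float)
    affine = np.column_stack([R, t])
    return AffineAnchorTransform(
        affine=affine,
        anchor_nodes=np.empty((0, 2)) if anchor_nodes is None else anchor_nodes,
        anchor_displacements=(
            np.empty((0, 2)) if anchor_displacements is None else anchor_displacements
        ),
        field_scale=min(rows, cols) / 4.0,
    )


def warp_section(
    section: SectionImage,
    transform: AffineAnchorTransform,
    background: float = 0.0,
) -> SectionImage:
    """Resample every channel through the transform (bilinear interpolation;
    out-of-bounds pixels set to the background level)."""
    rows, cols = section.shape
    yy, xx = np.mgrid[0:rows, 0:cols]
    pts = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)
    src = transform.invert(pts)
    coords = np.stack([src[:, 1].reshape(rows, cols), src[:, 0].reshape(rows, cols)])
    channels = {
        name: ndi.map_coordinates(
            arr, coords, order=1, mode="constant", cval=background
        )
        for name, arr in section.channels.items()
    }
    return SectionImage(
        channels=channels,
        pixel_size_um=section.pixel_size_um,
        modality=section.modality,
    )


def apply_random_transform(
    section: SectionImage,
    max_rotation_deg: float = 10.0,
    scale_range: tuple[float, float] = (0.95, 1.05),
    max_translation_px: float = 15.0,
    n_anchors: int = 0,
    anchor_jitter_px: float = 0.0,
    seed: int = 0,
    background: float | None = None,
) -> tuple[SectionImage, AffineAnchorTransform]:
    """Misalign a section: a sampled affine (rotation, scale, translation
    about the image center) followed by smooth local anchor displacements.

    Returns the warped image and the exact transform used, so registration
    can be tested against ground truth. Deterministic for a fixed seed.
    """
    if max_rotation_deg < 0 or max_translation_px < 0 or anchor_jitter_px < 0:
        raise ValueError("transform magnitudes must be nonnegative")
    if scale_range[0] <= 0:
        raise ValueError("degenerate scale range")
    rng = np.random.default_rng(seed)
    rot = rng.uniform(-max_rotation_deg, max_rotation_deg)
    scale = rng.uniform(*scale_range)
    trans = rng.uniform(-max_translation_px, max_translation_px, 2)
    rows, cols = section.shape
    base = make_transform((rows, cols), rot, scale, tuple(trans))
    if n_anchors > 0:
        side = int(np.ceil(np.sqrt(n_anchors)))
        gy = np.linspace(0.15 * rows, 0.85 * rows, side)
        gx = np.linspace(0.15 * cols, 0.85 * cols, side)
        nodes_in = np.array([[x, y] for y in gy for x in gx])[:n_anchors]
        nodes = apply_affine(base.affine, nodes_in)
        disp = rng.uniform(-anchor_jitter_px, anchor_jitter_px, (n_anchors, 2))
        transform = AffineAnchorTransform(
            affine=base.affine,
            anchor_nodes=nodes,
            anchor_displacements=disp,
            field_scale=min(rows, cols) / 4.0,
        )
    else:
        transform = base
    if background is None:
        background = float(
            np.median(
                np.concatenate(
                    [arr[0, :], arr[-1, :]]
                )
            )
            if (arr := next(iter(section.channels.values()))) is not None
            else 0.0
        )
    warped = warp_section(section, transform, background=background)
    return warped, transform
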