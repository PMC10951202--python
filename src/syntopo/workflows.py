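"""End-to-end pipelines over synthetic sections.

These functions wire the individual stages together exactly as the analysis
scripts and the validation harness run them: simulate a section over a toy
atlas, optionally misalign it, detect and measure cells, background-correct,
fit the mean±SD classifier, register back to the atlas, and aggregate
regional class prevalence. Every stage is the public API of its module; the
workflows only pass data along.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .atlas import AtlasPlate, RegionOntology
from .classify import classify_cells, fit_intensity_classifier
from .detect import (
    CellTable,
    auto_background_rois,
    detect_nuclei,
    measure_intensity,
    subtract_background,
)
from .quantify import region_class_prevalence
from .register import fit_affine_from_landmarks, map_cells_to_atlas, refine_with_anchors
from .synth import (
    AffineAnchorTransform,
    ClassMixture,
    GroundTruth,
    IntensityModel,
    apply_random_transform,
    make_toy_atlas,
    random_mixtures,
    render_if_section,
)


@dataclass
class SectionRun:
    """Everything one synthetic section run produces."""

    atlas: AtlasPlate
    ontology: RegionOntology
    truth: GroundTruth
    cells: CellTable
    stats: pd.DataFrame
    transform: AffineAnchorTransform | None = None
    detection_recall: float = float("nan")
    detection_precision: float = float("nan")


def match_detections(
    detected_xy: np.ndarray, true_xy: np.ndarray, tol_px: float = 3.0
) -> tuple[float, float]:
    """(recall, precision) by nearest-centroid matching within ``tol_px``."""
    if len(detected_xy) == 0 or len(true_xy) == 0:
        return 0.0, 0.0
    tree = cKDTree(true_xy)
    d, idx = tree.query(detected_xy)
    hit = d <= tol_px
    precision = float(hit.sum()) / len(detected_xy)
    recall = len(set(idx[hit].tolist())) / len(true_xy)
    return recall, precision


def default_landmark_grid(shape: tuple[int, int], n: int = 8) -> np.ndarray:
    """Deterministic spread of ``n`` landmark positions inside the plate."""
    rows, cols = shape
    side = int(np.ceil(np.sqrt(n)))
    gy = np.linspace(0.1 * rows, 0.9 * rows, side)
    gx = np.linspace(0.1 * cols, 0.9 * cols, side)
    pts = np.array([[x, y] for y in gy for x in gx])
    return pts[:n]


def run_section_pipeline(
    n_regions: int = 20,
    cells_per_region: int = 200,
    shape: tuple[int, int] = (512, 512),
    seed: int = 0,
    model: IntensityModel | None = None,
    mixtures: dict[int, ClassMixture] | None = None,
    perturb: bool = True,
    max_rotation_deg: float = 10.0,
    scale_range: tuple[float, float] = (0.95, 1.05),
    max_translation_px: float = 15.0,
    n_anchors: int = 9,
    anchor_jitter_px: float = 3.0,
    n_landmarks: int = 12,
    atlas: AtlasPlate | None = None,
    ontology: RegionOntology | None = None,
    level: int | None = None,
) -> SectionRun:
    """Simulate → (mis)align → detect → classify → register → quantify.

    One seed drives atlas, mixtures, section, and misalignment (offset into
    independent substreams). Landmarks and anchors for the registration are
    sampled from the ground-truth transform — standing in for the
    human-placed correspondences of an interactive alignment.
    """
    if model is None:
        model = IntensityModel()
    if atlas is None or ontology is None:
        atlas, ontology = make_toy_atlas(n_regions, shape, seed=seed)
    if mixtures is None:
        region_ids = [int(r) for r in np.unique(atlas.labels) if r != 0]
        mixtures = random_mixtures(region_ids, seed=seed + 1)
    section, truth = render_if_section(
        atlas, mixtures, cells_per_region, model=model, seed=seed + 2
    )
    transform = None
    if perturb:
        section, transform = apply_random_transform(
            section,
            max_rotation_deg=max_rotation_deg,
            scale_range=scale_range,
            max_translation_px=max_translation_px,
            n_anchors=n_anchors,
            anchor_jitter_px=anchor_jitter_px,
            seed=seed + 3,
            background=model.background,
        )
    cells = detect_nuclei(section)
    true_xy = truth.cells[["x", "y"]].to_numpy()
    if transform is not None:
        true_xy = transform.apply(true_xy)
    recall, precision = match_detections(
        cells.df[["x", "y"]].to_numpy(), true_xy
    )
    cells = measure_intensity(cells, section, "signal", "nuclear")
    rois = auto_background_rois(cells, section.shape)
    cells = subtract_background(cells, section, "signal", rois)
    classifier = fit_intensity_classifier(
        cells, "signal", "nuclear", corrected=True
    )
    cells = classify_cells(classifier, cells, corrected=True)
    if transform is not None:
        grid = default_landmark_grid(atlas.shape, n_landmarks)
        lm_src, lm_dst = transform.landmark_pairs(grid)
        linear = fit_affine_from_landmarks(lm_src, lm_dst)
        anchor_grid = default_landmark_grid(atlas.shape, 9) + 13.0
        an_src, an_dst = transform.landmark_pairs(anchor_grid)
        registration = refine_with_anchors(linear, list(zip(an_src, an_dst)))
    else:
        registration = refine_with_anchors(
            np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]), []
        )
    cells = map_cells_to_atlas(cells, registration, atlas)
    stats = region_class_prevalence(cells, ontology, level=level)
    return SectionRun(
        atlas=atlas,
        ontology=ontology,
        truth=truth,
        cells=cells,
        stats=stats,
        transform=transform,
        detection_recall=recall,
        detection_precision=precision,
    )


def prevalence_recovery(run: SectionRun) -> pd.DataFrame:
    """Per-region recovered vs true high-class prevalence (percentage points)."""
    true_high = {
        rid: 100.0 * m.as_array()[2] for rid, m in run.truth.mixtures.items()
    }
    rows = []
    for _, rec in run.stats.iterrows():
        rid = int(rec["region_id"])
        if rid == 0 or rid not in true_high:
            continue
        rows.append(
            {
                "region_id": rid,
                "true_prev_high": true_high[rid],
                "recovered_prev_high": rec["prev_high"],
                "abs_error": abs(rec["prev_high"] - true_high[rid]),
                "n_total": rec["n_total"],
            }
        )
    return pd.DataFrame(rows)


def paired_modality_sections(
    n_regions: int = 20,
    cells_per_region: int = 200,
    shape: tuple[int, int] = (512, 512),
    seed: int = 0,
    model: IntensityModel | None = None,
) -> tuple[SectionRun, SectionRun]:
    """Two modality runs (e.g. transcript vs protein) over one atlas with a
    shared latent per-region class mixture — the input to a concordance
    analysis with known ground truth."""
    atlas, ontology = make_toy_atlas(n_regions, shape, seed=seed)
    region_ids = [int(r) for r in np.unique(atlas.labels) if r != 0]
    mixtures = random_mixtures(region_ids, seed=seed + 1)
    run_a = run_section_pipeline(
        seed=seed + 10,
        cells_per_region=cells_per_region,
        model=model,
        mixtures=mixtures,
        atlas=atlas,
        ontology=ontology,
        perturb=False,
    )
    run_b = run_section_pipeline(
        seed=seed + 20,
        cells_per_region=cells_per_region,
        model=model,
        mixtures=mixtures,
        atlas=atlas,
        ontology=ontology,
        perturb=False,
    )
    return run_a, run_b
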