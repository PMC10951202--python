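#!/usr/bin/env python
"""Register the misaligned section back to the atlas from landmark/anchor
pairs, map every section's cells into regions, and build the per-region
class-prevalence tables. Also trains the chromogenic pixel classifier and
reports the relative positive-cell density.

Writes RegionStats CSVs under results/stats/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from syntopo.atlas import AtlasPlate, load_ontology
from syntopo.classify import count_positive_particles, train_pixel_classifier
from syntopo.detect import CellTable
from syntopo.image import SectionImage, load_label_raster
from syntopo.quantify import region_class_prevalence, relative_density
from syntopo.register import (
    fit_affine_from_landmarks,
    load_landmarks,
    map_cells_to_atlas,
    refine_with_anchors,
)

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    out = ROOT / "stats"
    out.mkdir(parents=True, exist_ok=True)
    ontology = load_ontology(ROOT / "sim" / "ontology.csv")
    plate = AtlasPlate(labels=load_label_raster(ROOT / "sim" / "atlas_labels.tif"),
                       ontology=ontology)
    identity = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])

    for name in ("rna", "protein"):
        cells = CellTable.from_csv(ROOT / "cells" / f"cells_{name}.csv")
        cells = map_cells_to_atlas(cells, refine_with_anchors(identity, []), plate)
        stats = region_class_prevalence(cells, ontology)
        stats.to_csv(out / f"stats_{name}.csv", index=False)
        print(f"{name}: {int((stats.region_id != 0).sum())} regions quantified")

    src, dst = load_landmarks(ROOT / "sim" / "landmarks.json")
    linear = fit_affine_from_landmarks(src, dst)
    a_src, a_dst = load_landmarks(ROOT / "sim" / "anchors.json")
    registration = refine_with_anchors(linear, list(zip(a_src, a_dst)))
    registration.to_json(out / "registration_misaligned.json")
    cells = CellTable.from_csv(ROOT / "cells" / "cells_misaligned.csv")
    cells = map_cells_to_atlas(cells, registration, plate)
    stats = region_class_prevalence(cells, ontology)
    stats.to_csv(out / "stats_misaligned.csv", index=False)
    n_un = int(cells.df["unassigned"].sum())
    print(f"misaligned: registered ({registration.nonlinear_kind} refinement), "
          f"{n_un} cells unassigned")

    mixtures = pd.read_csv(ROOT / "sim" / "mixtures.csv")
    merged = stats.merge(mixtures, on="region_id")
    err = (merged.prev_high - 100.0 * merged.pi_high).abs()
    print(f"prev_high recovery vs truth: median {err.median():.2f} pp, "
          f"max {err.max():.2f} pp, {100 * (err <= 5).mean():.0f}% within 5 pp")

    imgs, masks = [], []
    for i in range(3):
        sec = SectionImage.load(ROOT / "sim" / f"dab_train_{i}.tif")
        dab = sec.channel("dab")
        imgs.append(dab)
        masks.append({"positive": dab < 120, "negative": dab > 200})
    clf = train_pixel_classifier(imgs, masks, scales=(1.0, 2.0))
    eval_sec = SectionImage.load(ROOT / "sim" / "dab_eval.tif")
    count, areas = count_positive_particles(eval_sec.channel("dab"), clf)
    import json

    truth = json.loads((ROOT / "sim" / "truth_dab_meta.json").read_text())
    density = relative_density(count, truth["hematoxylin_count"])
    pd.DataFrame(
        [{"n_positive": count, "n_hematoxylin": truth["hematoxylin_count"],
          "relative_density_pct": density}]
    ).to_csv(out / "dab_density.csv", index=False)
    print(f"DAB: counted {count} positive particles "
          f"(truth {truth['dab_positive_count']}); relative density "
          f"{density:.1f}% of {truth['hematoxylin_count']} hematoxylin+ cells")


if __name__ == "__main__":
    main()
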