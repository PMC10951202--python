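#!/usr/bin/env python
"""Generate the study's synthetic inputs: a 20-region toy atlas, two
modality sections (transcript and protein) sharing one latent per-region
class mixture, a misaligned section with its true transform, and a
chromogenic (DAB/hematoxylin) image pair.

Writes everything under results/sim/ with full ground truth.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from syntopo.image import SectionImage, save_label_raster
from syntopo.register import save_landmarks
from syntopo.synth import (
    apply_random_transform,
    make_toy_atlas,
    random_mixtures,
    render_dab_section,
    render_if_section,
)
from syntopo.workflows import default_landmark_grid

SEED = 7
OUT = Path(__file__).resolve().parents[1] / "results" / "sim"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    plate, ontology = make_toy_atlas(20, (512, 512), seed=SEED)
    save_label_raster(plate.labels, OUT / "atlas_labels.tif")
    ontology.save(OUT / "ontology.csv")
    areas = np.bincount(plate.labels.ravel())[1:]
    print(f"atlas: 20 regions, areas {areas.min()}-{areas.max()} px")

    mixtures = random_mixtures(range(1, 21), seed=SEED + 1)
    pd.DataFrame(
        [
            {"region_id": r, "pi_low": m.low, "pi_med": m.medium, "pi_high": m.high}
            for r, m in mixtures.items()
        ]
    ).to_csv(OUT / "mixtures.csv", index=False)

    for name, seed in (("rna", SEED + 2), ("protein", SEED + 3)):
        section, truth = render_if_section(plate, mixtures, 200, seed=seed)
        section.save(OUT / f"section_{name}.tif")
        truth.save(OUT, stem=f"truth_{name}")
        print(f"{name} section: {len(truth.cells)} cells rendered")

    section, truth = render_if_section(plate, mixtures, 200, seed=SEED + 4)
    truth.save(OUT, stem="truth_misaligned")
    warped, transform = apply_random_transform(
        section, max_rotation_deg=10.0, scale_range=(0.95, 1.05),
        max_translation_px=15.0, n_anchors=9, anchor_jitter_px=3.0,
        seed=SEED + 5, background=20.0,
    )
    warped.save(OUT / "section_misaligned.tif")
    (OUT / "true_transform.json").write_text(json.dumps(transform.to_json(), indent=1))
    lm_src, lm_dst = transform.landmark_pairs(default_landmark_grid((512, 512), 12))
    save_landmarks(lm_src, lm_dst, OUT / "landmarks.json")
    an_src, an_dst = transform.landmark_pairs(default_landmark_grid((512, 512), 9) + 13.0)
    save_landmarks(an_src, an_dst, OUT / "anchors.json")
    print("misaligned section + true transform + landmark/anchor pairs written")

    for i in range(3):
        dab, hema, t = render_dab_section(40, 150, size_range_px=(8, 16),
                                          shape=(256, 256), seed=SEED + 10 + i)
        SectionImage({"dab": dab, "hematoxylin": hema}, modality="DAB").save(
            OUT / f"dab_train_{i}.tif"
        )
    dab, hema, t = render_dab_section(50, 200, size_range_px=(8, 16),
                                      shape=(512, 512), seed=SEED + 20)
    SectionImage({"dab": dab, "hematoxylin": hema}, modality="DAB").save(
        OUT / "dab_eval.tif"
    )
    t.save(OUT, stem="truth_dab")
    print(f"DAB pair: {t.dab_positive_count} positive particles, "
          f"{t.hematoxylin_count} hematoxylin nuclei")


if __name__ == "__main__":
    main()
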