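#!/usr/bin/env python
"""Render anatomical heatmaps of the regional statistics: high-class
prevalence per modality plus the registered misaligned section, each as PNG
with a JSON colorbar sidecar under results/heatmaps/."""

from pathlib import Path

import pandas as pd

from syntopo.atlas import AtlasPlate, load_ontology
from syntopo.heatmap import render_region_heatmap, save_heatmap
from syntopo.image import load_label_raster

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    out = ROOT / "heatmaps"
    out.mkdir(parents=True, exist_ok=True)
    ontology = load_ontology(ROOT / "sim" / "ontology.csv")
    plate = AtlasPlate(
        labels=load_label_raster(ROOT / "sim" / "atlas_labels.tif"),
        ontology=ontology,
    )
    for name in ("rna", "protein", "misaligned"):
        stats = pd.read_csv(ROOT / "stats" / f"stats_{name}.csv")
        rgb, meta = render_region_heatmap(
            stats, plate, statistic="prev_high", vmin=0.0, vmax=60.0
        )
        save_heatmap(rgb, meta, out / f"prev_high_{name}.png")
        print(f"{name}: heatmap of prev_high "
              f"(range {meta['vmin']:.0f}-{meta['vmax']:.0f}%)")


if __name__ == "__main__":
    main()
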