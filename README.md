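# syntopo

Cell-level expression topography across a labeled anatomical atlas.

`syntopo` is a tested re-implementation of the quantitative workflow used to
map how strongly individual cells express a protein or transcript across
brain regions: nuclei are detected in section images, each cell's signal
intensity is measured and background-corrected, cells are classified into
**low / medium / high** expressors, sections are registered onto an atlas
plate, and class prevalence is aggregated per region and compared between
modalities (e.g. RNA in situ hybridization vs protein immunofluorescence).
It is aimed at quantitative neuroanatomy work of the QuPath → QuickNII →
VisuAlign → Nutil style, re-cast as a reproducible library plus CLI, and it
ships a synthetic-data generator with exportable ground truth so every stage
is testable without any imaging data.

## The statistics at the core

* **Three-class intensity rule.** With per-cell intensities \(I_1..I_n\),
  the classifier uses the pool mean \(\mu\) and sample SD \(\sigma\)
  (n−1 denominator): a cell is *low* if \(I < \mu-\sigma\), *high* if
  \(I > \mu+\sigma\), *medium* otherwise (boundaries are medium).
* **Background correction.** The mean intensities of ≥1 signal-negative
  ROIs are averaged and subtracted from each cell's measurement; results
  clamp at 0.
* **Region prevalence.** For each atlas region,
  \( \mathrm{prev}_c = 100 \cdot n_c / n_\mathrm{total} \); regions with no
  cells report *absent*, not 0.
* **Relative chromogenic density.** \(100 \cdot n_{+} / n_\mathrm{hematoxylin}\),
  where positive particles are connected components of a pixel-classifier
  mask with area strictly greater than 5 px.
* **Registration.** A least-squares affine from landmark pairs, refined by a
  thin-plate-spline displacement field that maps every anchor source exactly
  onto its target; cell centroids are warped and assigned the label of the
  nearest atlas pixel.
* **Concordance.** Pearson r between two modalities' regional prevalence,
  with OLS fit line and 95% prediction intervals
  \(\hat y \pm t_{0.975,\,n-2}\, s \sqrt{1 + 1/n + (x-\bar x)^2/S_{xx}}\),
  plus two-way ANOVA (Type II) with Tukey–Kramer post hoc for group
  comparisons.

## Worked example

```python
import syntopo as st

plate, ontology = st.make_toy_atlas(20, (512, 512), seed=42)
mixtures = st.random_mixtures(range(1, 21), seed=42)
section, truth = st.render_if_section(plate, mixtures, 200, seed=42)

cells = st.detect_nuclei(section)                       # 3936 cells
cells = st.measure_intensity(cells, section, "signal", "nuclear")
from syntopo.detect import auto_background_rois
cells = st.subtract_background(cells, section, "signal",
                               auto_background_rois(cells, section.shape))
clf = st.fit_intensity_classifier(cells, "signal", "nuclear", corrected=True)
print(clf.mu, clf.sd)                                   # 101.5 42.3
cells = st.classify_cells(clf, cells, corrected=True)

import numpy as np
reg = st.refine_with_anchors(np.array([[1., 0, 0], [0, 1., 0]]), [])
cells = st.map_cells_to_atlas(cells, reg, plate)
stats = st.region_class_prevalence(cells, ontology)
print(stats.head(3)[["region_id", "n_total", "prev_high"]])
```

On this synthetic section, detection recovers 98–99% of the 4 000 planted
nuclei with no false positives, and each region's recovered `prev_high` sits
within a few percentage points of the mixture weight the generator used —
the kind of ground-truth check the package's test suite runs routinely.
The same chain is scripted end to end in `analysis/01_simulate.py` …
`05_heatmaps.py`, which print their findings and write tables, heatmaps and
provenance sidecars under `results/`.

A shell interface wraps the same functions:

```sh
syntopo simulate --config examples/scenario.yaml --out run/
syntopo detect --image run/section_misaligned.tif --channel nuclear \
        --measure signal --out run/cells.csv
syntopo classify --cells run/cells.csv --out run/cells.csv
syntopo register --cells run/cells.csv --landmarks run/landmarks.json \
        --anchors run/anchors.json --atlas run/atlas_labels.tif \
        --ontology run/ontology.csv --out run/cells.csv
syntopo quantify --cells run/cells.csv --ontology run/ontology.csv \
        --out run/stats.csv
syntopo heatmap --stats run/stats.csv --atlas run/atlas_labels.tif \
        --ontology run/ontology.csv --statistic prev_high --out run/map.png
```

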