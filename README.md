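# tissuemux

Single-cell and pixel-level analysis of multiplexed tissue images.

Multiplexed imaging technologies — imaging mass cytometry (IMC), MIBI, CODEX
and multiplexed immunofluorescence (mIF) — measure dozens of protein markers
over a tissue section at subcellular resolution. Turning those intensity
channels into biology requires a chain of steps that are usually spread over
several tools: channel normalisation, background removal, tissue-compartment
masking, single-cell segmentation, phenotyping, spatial statistics and
cell-agnostic area quantification. `tissuemux` implements that whole chain as
one pipeline for researchers analysing multiplexed tissue data, with every
stage callable from Python, from a YAML-configured CLI, or replaceable by
external inputs (e.g. a label image from a deep-learning segmenter).

## What it computes

* **Normalisation** — each channel is rescaled to its 99th intensity
  percentile: `v ← min(v / P₉₉, 1)`, per image or pooled across samples.
* **Masks** — Otsu and multi-class Otsu thresholds (256-bin histograms) plus
  morphological recipes (Gaussian smoothing, disk dilation/opening, hole
  filling, union/subtract/intersect) build compartment masks such as lamina
  propria or epithelium from structural markers.
* **Segmentation** — nuclei from the DNA channel (4-connected components,
  equivalent-diameter filter `2√(A/π)`), expanded to whole cells radially
  over a membrane mask, by watershed seeded on the nuclei, or isotropically
  by a fixed distance; per-cell mean marker intensities and centroids follow.
* **Phenotyping** — cells are assigned to compartments and types by mask
  overlap fractions (boundaries inclusive), gated with boolean
  marker-threshold expressions (`CD8 >= 0.01 & PD1 >= 0.005`), or clustered
  on z-scored expression via PCA → kNN graph → Louvain at a chosen
  resolution.
* **Spatial statistics** — homotypic aggregation by DBSCAN (reachability
  radius `ε = √(minPts/(π·ρ))` from a density `ρ` in cells/mm²); heterotypic
  nearest-centroid distances; group comparisons by two-sided Wilcoxon
  rank-sum with Benjamini–Hochberg FDR and a biological relevance rule
  (|Δ median| ≥ 8 µm, roughly a lymphocyte diameter); and a permutation null
  that reshuffles cell identities within each sample, with
  `p = (1 + #{|δ*| ≥ |δ|}) / (K + 1)`.
* **Pixel analysis** — the fraction of a compartment positive for a boolean
  combination of marker masks, for signal (e.g. secreted IgA) that no
  cell-based analysis can see.

A synthetic-tissue generator (`tissuemux.synthetic`) produces fixtures with
exact ground truth — disk cells with nuclei, per-type marker expression,
compartments, and grouped samples with exchangeable identities — so the whole
pipeline is testable without any imaging data.

## Worked example

```python
import tissuemux as tm

spec = tm.TissueSpec(
    image_size=(400, 400), pixel_size_um=1.0,
    cell_types=(
        tm.CellTypeSpec("T_cell", count=18, radius_px=5, nucleus_radius_px=2.5,
                        expression={"CD3": (1.0, 0.02)}),
        tm.CellTypeSpec("B_cell", count=18, radius_px=5, nucleus_radius_px=2.5,
                        expression={"CD20": (1.0, 0.02)}),
        tm.CellTypeSpec("macrophage", count=18, radius_px=5, nucleus_radius_px=2.5,
                        expression={"CD68": (1.0, 0.02)}),
    ),
    noise_sd=0.02, seed=0,
)
stack, truth, masks = tm.generate_tissue(spec, sample_id="demo")

params = tm.SegmentationParams(nucleus_channel="DNA", min_diameter_px=4,
                               max_diameter_px=60, expansion="isotropic",
                               expansion_px=3)
nuclei = tm.detect_nuclei(stack, params)
labels = tm.expand_cells(nuclei, stack, params)
cells = tm.extract_features(labels, stack)
print(f"detected {labels.n_cells} cells (planted {len(truth)})")

for name, marker in [("T_cell", "CD3"), ("B_cell", "CD20"), ("macrophage", "CD68")]:
    gated = tm.gate_cells(cells, tm.GateSpec(name, f"{marker} >= 0.5"))
    cells.loc[cells.cell_id.isin(gated.cell_id), "cell_type"] = name
print(cells.cell_type.value_counts().to_string())

dist = tm.nearest_distances(cells[cells.cell_type == "T_cell"],
                            cells[cells.cell_type == "B_cell"])
print(f"median T-cell to nearest-B-cell distance: "
      f"{dist.nearest_distance_um.median():.1f} um")

mask, t = tm.threshold_otsu(stack.channel("CD3"), name="CD3")
area = tm.positive_area({"CD3": mask}, "CD3", "image", sample_id="demo")
print(f"CD3-positive pixel fraction: {area.fraction:.4f} (Otsu t={t:.3f})")
```

Output:

```
detected 54 cells (planted 54)
cell_type
T_cell        18
macrophage    18
B_cell        18
median T-cell to nearest-B-cell distance: 54.9 um
CD3-positive pixel fraction: 0.0091 (Otsu t=0.096)
```

Every planted cell is recovered and correctly typed; the CD3⁺ pixel fraction
(0.91 % of the field) reflects the 18 T-cell disks of radius 5 px in a
400×400 image.

The same pipeline runs from the command line against a YAML configuration:

```bash
tissuemux run-all --config run.yaml            # all stages
tissuemux segment --config run.yaml            # one stage
tissuemux run-all --config run.yaml --stages spatial,pixel
```

Stages read and write files in the configured output directory, so any stage
can be skipped and fed external data (a segmentation label image, a cell
table) instead.

## Documentation

`docs/methods.md` describes the models, parameter choices, numerical
conventions and known limitations in detail.
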