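# flarequant

Per-cell quantification of fluorescent lipid-associated reporters (FLAREs) in
yeast fluorescence microscopy. The package implements the image analyses used
to study plasma-membrane (PM) stress responses in budding yeast — the
redistribution of PI(4,5)P2, phosphatidylserine, PI(4)P and accessible-sterol
reporters between the PM, PM invaginations and the cell interior — together
with a synthetic-microscopy generator that provides exact ground truth, so
every stage of the pipeline is verifiable without any real image data.

It is written for microscopists and image analysts who need reproducible,
scriptable versions of the usual point-and-click quantifications: per-cell
colocalization, membrane/cytoplasm ratios, line-profile sorting coefficients,
high-content invagination screens, lipid-droplet volumetry and kymographs.

## What it computes

Given a two-channel image (a *tested* reporter and a *reference* PM marker
such as 2xPH<sup>PLCδ</sup>) and a per-cell label mask:

- **Colocalization** — Pearson's correlation coefficient (PCC) of the two
  channels over all pixels of each cell mask, with no intensity threshold.
  Cells intersected by the image border are excluded. Condition comparisons
  are made on per-experiment mean PCCs (Shapiro–Wilk normality check, then an
  unpaired two-sample *t* test), never on pooled cells.
- **PM/cytoplasm enrichment** — after subtracting a median-filtered duplicate
  of the image (101 px kernel) as background, the ratio
  x̄<sub>PM</sub> / x̄<sub>cytoplasm</sub> of mean intensities in a ring-shaped
  peripheral ROI and an eroded internal ROI, per cell.
- **Sorting coefficient** — for one PM invagination per cell,

  sorting coefficient = (F<sub>tested</sub>/F<sub>ref</sub>)<sub>invagination</sub> ÷ (F<sub>tested</sub>/F<sub>ref</sub>)<sub>PM patch</sub>

  where each *F* is a background-subtracted fluorescence density integrated
  along a line profile; 1 means no differential sorting, and the statistic is
  invariant to independent rescaling of either channel.
- **Invagination screen statistic** — white top-hat enhancement of the
  reference channel, per-cell segmentation of invaginations, the invagination
  area sum normalized to the cell area, and normalization of condition means
  to vehicle-treated cells at the matched timepoint and experiment.
- **Lipid-droplet volumetry** — 3-D connected components above a threshold in
  a z-stack; object volume = voxel count × voxel volume; per-cell totals in µm³.
- **Kymographs** — intensity along a fixed line over the frames of a
  timelapse (rows = time, columns = position).

The `synthgen` module paints elliptical yeast-like cells (bright PM ring,
optional finger-shaped PM invaginations, intracellular foci), applies a
Poisson–Gaussian camera model, and records every generative parameter and
region mask, including internalization kinetics of the tested reporter after
a treatment time. See `docs/methods.md` for the model and its defaults.

## Worked example

```python
import numpy as np
import flarequant as fq
from flarequant.synthgen import truth_profile_lines
from flarequant.sorting_kymo import LineROI, extract_profile, sorting_coefficient
from flarequant.segmentation import make_rois
from flarequant.enrichment import median_background_subtract, pm_enrichment
from flarequant.coloc import pcc_per_cell

# two cells; the first carries a PM invagination with 3-fold reporter sorting
specs = [
    fq.CellSpec(center=(60, 60), pm_fraction=0.6, n_invaginations=1, sorting_factor=3.0),
    fq.CellSpec(center=(60, 180), pm_fraction=0.6),
]
stack, mask, truth = fq.generate_field(specs, fq.NoiseSpec(seed=1), shape=(128, 240))
tested, ref = stack.channel("tested"), stack.channel("reference")

for r in pcc_per_cell(tested, ref, mask):
    print(f"cell {r.label}: PCC = {r.pcc:.3f} over {r.n_pixels} px")

rois = make_rois(mask, ring_width_px=3, erosion_depth_px=6)
sub = median_background_subtract(tested, kernel_px=101)
e = pm_enrichment(sub, rois)[1]  # the plain cell
print(f"cell {e.label}: PM/cytoplasm ratio = {e.ratio:.2f} "
      f"(true contrast {truth.pm_contrast[e.label]:.2f})")

lines = truth_profile_lines(truth, 1)
roi_i = LineROI(tuple(lines["invagination"]), step_px=0.5, half_width_px=0)
roi_p = LineROI(tuple(lines["pm"]), step_px=0.5, half_width_px=0)
bg = (float(np.median(tested[mask.data == 0])), float(np.median(ref[mask.data == 0])))
m = sorting_coefficient(
    extract_profile(tested, roi_i), extract_profile(ref, roi_i),
    extract_profile(tested, roi_p), extract_profile(ref, roi_p), background_rule=bg)
print(f"sorting coefficient = {m.sorting_coefficient:.2f} (true factor 3.0)")
```

prints

```
cell 1: PCC = 0.872 over 1373 px
cell 2: PCC = 0.988 over 1373 px
cell 2: PM/cytoplasm ratio = 6.62 (true contrast 6.66)
sorting coefficient = 2.79 (true factor 3.0)
```

Both cells colocalize strongly with the PM marker (the invagination-bearing
cell slightly less, since the sorted reporter deviates from the reference
there). The plain cell's measured PM/cytoplasm ratio recovers the generator's
analytic contrast to within 1%, and the line-profile sorting coefficient
recovers the painted 3-fold sorting within the shot-noise scatter of a single
cell (the median over many cells converges to 3.0).

## Command line

`flarequant` exposes each stage as a subcommand:

```bash
flarequant simulate timelapse --seed 1 --out sim/
flarequant segment --in sim/image.tif --out mask.tif
flarequant coloc --images tested.tif ref.tif --mask mask.tif --out cells.csv
flarequant enrich --image tested.tif --mask mask.tif --kernel 101 --out enrich.csv
flarequant invag --image ref.tif --mask mask.tif --vehicle DMSO --out invag.csv
flarequant sort --images tested.tif ref.tif --rois rois.json --out sorting.csv
flarequant kymo --timelapse sim/image.tif --roi roi.json --out kymo.tif
flarequant droplets --stack z.tif --voxel 0.2 0.1 0.1 --out ld.csv
flarequant run --seed 1 --out demo/   # end-to-end simulate → quantify → summarize
```

`flarequant run` simulates a treated and a vehicle arm, quantifies all
measures pre- and post-treatment, and writes a tidy per-cell CSV, a summary
CSV, kymograph TIFFs and a provenance JSON sufficient to reproduce the run
bit-exactly.

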