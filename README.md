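# cystscreen

Analysis pipeline for 3D cyst-growth high-content screens, as used in
polycystic kidney disease (PKD) drug discovery.  Renal epithelial cells grown
in a hydrogel form hollow spherical cysts — an actin-rich wall around a
fluid-filled lumen — that swell when cAMP signalling is stimulated with
forskolin.  A screen images each well of a 384-well plate as a two-channel
z-stack (actin ring + nuclei) and asks, per compound and dose, whether the
forskolin-induced swelling is prevented, untouched, or replaced by something
else entirely (shrunken, disintegrated cysts with few nuclei — a likely
cytotoxic "novel phenotype").

`cystscreen` implements the full quantification chain plus a seed-controlled
synthetic screen generator with exhaustive ground truth, so every step can be
validated against known truth even though raw screen imagery is rarely
shareable.

## What it computes

* **Segmentation** — per-plane masks (smooth → three-class Otsu threshold →
  fill the dim lumen → size filter), linked across adjacent planes by mask
  overlap so vertically overlapping cysts are resolved as distinct objects;
  each cyst is measured on its best-focus (equatorial) plane, including the
  actin-dense wall band and nuclei counts from maximum intensity projections.
* **Per-well phenotypic features** — robust aggregates (median, MAD) of area,
  perimeter, circularity `4πA/P²`, wall thickness and fractions, and
  projection intensities, plus object and nuclei counts.
* **Normalization** — z-score to plate medians, then to the
  unstimulated-control median, or percent inhibition
  (unstimulated median → 100 %, forskolin-stimulated median → 0 %).
* **Assay QC** — the replicate-adjusted Z′-factor

  ```
  Z' = [(AVG_max − 3·SD_max/√n) − (AVG_min + 3·SD_min/√n)] / (AVG_max − AVG_min)
  ```

  between stimulated (max) and unstimulated (min) control groups, with n
  technical replicates (classical Z′ at n = 1).
* **Hit calling** — a compound is a hit when its replicate-mean cyst-size
  z-score (relative to the unstimulated-control median) is ≤ 0 at any tested
  dose.
* **Phenotype profiling** — features gated by the Z′ between stimulated and
  reference-inhibitor controls (cutoff −1.0), standardized, condensed to three
  principal components; compound–dose conditions classified as
  `restored` / `unchanged` / `novel` against the control centroids, with a
  low-nuclei-count override flagging cytotoxicity.
* **Synergy** — Bliss independence `E = E_A + E_B − E_A·E_B` and the
  combination index `CI = (E_A + E_B − E_A·E_B)/E_AB` (CI < 1 synergy,
  CI > 1 antagonism) over two-compound dose grids.

## Worked example

The bundled demo config simulates a 32-well plate region (a full-effect
active, an inert compound and a cytotoxicant, each at 0.1 and 1 µM in
quadruplicate, plus controls), writes per-well TIFF stacks, and runs the
whole chain:

```bash
cystscreen run-all --config configs/demo.yaml --seed 1 --outdir scratch/demo
```

```
plate P1: Z' (replicate-adjusted) = 0.530
```

`scratch/demo/hits.csv` then contains (columns abridged):

```
treatment  concentration_um  mean_size_z  dose_hit   hit
   active               0.1    -0.090194      True  True
   active               1.0     0.113722     False  True
    inert               0.1    13.446679     False False
    inert               1.0    18.062235     False False
 toxicant               0.1    -7.917424      True  True
 toxicant               1.0    -7.874287      True  True
```

The active compound suppresses swelling back to the unstimulated median
(mean z ≈ 0; ≤ 0 at 0.1 µM, so the "hit at either dose" rule fires); the
inert compound leaves wells fully swollen (z ≫ 0).  The toxicant also
"inhibits" by size — which is why hit lists need the phenotype labels in
`scratch/demo/phenotype_labels.csv`:

```
treatment  concentration_um  mean_nuclei_count     label
   active               1.0               62.5  restored
    inert               1.0               71.5 unchanged
 toxicant               1.0               22.5     novel
```

The cytotoxicant's nuclei count collapses and its wells sit far from both
control centroids in PC space: a novel phenotype, not a genuine rescue.

Python API sketch:

```python
import cystscreen as cs

res = cs.analyze_screen(cs.desk_screen_config(seed=1), cs.desk_compounds())
print(res.zprime, res.hits, res.labels)
```

## Layout

```
src/cystscreen/
  simulate.py       synthetic plates, cysts, dose-response, rendering
  stacks.py         ImageStack container, TIFF I/O, max projection
  segmentation.py   plane segmentation, vertical linking, wall band, nuclei
  features.py       per-object descriptors, per-well aggregation
  normalization.py  plate/control z-scores, percent inhibition, Z', hits
  profiling.py      Z'-gated feature selection, PCA space, classification
  synergy.py        Bliss prediction, combination index, dose grids
  pipeline.py       stage orchestration, manifest, in-memory analysis
  cli.py            `cystscreen` command group
```

See `docs/methods.md` for the modelling assumptions, parameter defaults and
known limitations.
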