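# Methods

## The assay being modelled

Renal epithelial cells embedded in a 3D hydrogel form hollow cysts: a sphere
with an F-actin-dense wall around a dim lumen.  Raising intracellular cAMP
with forskolin drives fluid secretion and swelling; candidate inhibitors are
co-applied and scored by how far they pull cyst size back toward the
unstimulated state.  Wells are imaged at low magnification as z-stacks
(~25 focal planes, 50 µm apart) in an actin channel and a nuclei channel.
At this resolution a cyst appears on a handful of adjacent planes as a bright
ring; nuclei are unresolved point-like spots best read from a maximum
intensity projection.

## Segmentation model

Cysts are segmented plane-by-plane and then linked along z:

1. **Per-plane masks.** Each plane is Gaussian-smoothed (σ = 0.8 px) and
   thresholded at the upper split of a three-class Otsu decomposition
   (background / lumen / wall).  The two-class split is selectable but lands
   between background and lumen, dilating masks by about a pixel; the upper
   split puts the boundary at the wall edge (≤ 4 % area error on rendered
   discs of radius 5–40 px).  Because any histogram threshold is meaningless
   on a plane with no object, the effective threshold is floored at the plane
   median + 6 robust SDs (1.4826·MAD) of the smoothed plane, plus an optional
   absolute floor.  Both floors are inert when real foreground is present and
   on noise-free images.  The ring is closed into a filled region
   (hole-filling), so "area" means whole-cyst cross-section, lumen included;
   components outside [min_area, max_area] are dropped and border-touching
   objects are flagged (and excluded from well aggregates by default, since
   clipped objects bias area).  A constant plane yields no objects, not an
   error.
2. **Vertical linking.** Objects on adjacent planes belong to the same cyst
   when their pixel overlap is ≥ 0.5 of the smaller mask; each object accepts
   at most one link per neighbouring plane (largest overlap, ties to the
   lower label), and linked groups are merged by union-find.  Objects that
   coincide in x,y but appear on non-adjacent planes therefore remain
   distinct — the vertically overlapping case that a single whole-stack
   projection would fuse.
3. **Best-focus measurement.** Each linked group is measured on its
   maximal-area plane (the sphere's equator; ties to the lower plane index):
   pixel area, perimeter, centroid, and the wall band.
4. **Wall band.** Within the mask dilated by 1 px, wall pixels are those
   brighter than the interior (lumen) median plus half the interior-to-peak
   contrast; the interior is read from the mask eroded by max(2, r_eq/3) px.
   Mean wall thickness = wall area / perimeter.  A uniform-intensity object
   has no actin-dense band and gets thickness ≈ 0; masks below the minimum
   area return thickness 0 with a degenerate flag.
5. **Nuclei.** The nuclei stack is collapsed to a maximum intensity
   projection, smoothed (σ = 1.5 px), thresholded (Otsu with the same noise
   floor), cleaned of sub-4-px specks, and counted as local intensity maxima
   at ≥ 3 px spacing so touching spots split.  Deterministic throughout.

Coordinates are 0-based pixel-grid row-major; areas are raw pixel counts.

## Features and normalization

Per-object descriptors: area, perimeter, circularity 4πA/P² (clipped to 1,
undefined for zero perimeter), wall thickness, wall-area fraction,
wall-to-size ratio (thickness / equivalent radius), and mean/max actin
intensity over the mask in the projection.  Wells are summarised by median
and normal-consistent MAD (cyst populations are outlier-prone); mean area is
kept alongside because screen readouts are conventionally reported as well
means.  A well with zero objects keeps its record with missing aggregates —
emptiness is a cytotoxicity signal, not bad data.

Normalization is two-step: per plate and feature, (x − plate median)/scale;
then (x − unstimulated-control median)/control scale.  The default scale is
1.4826·MAD with classical SD selectable — the screen protocol says
"z-scored" without naming a scale, so both are provided and recorded in the
table provenance.  Percent inhibition is the linear map sending the
stimulated-control median to 0 % and the unstimulated-control median to
100 %, deliberately unclamped (over-inhibition is a phenotype signal;
clamping happens only when effects enter Bliss arithmetic, which needs
probabilities).

## Assay quality and hit calling

Assay robustness is the replicate-adjusted Z′-factor,

    Z' = [(AVG_max − 3·SD_max/√n) − (AVG_min + 3·SD_min/√n)]
         / (AVG_max − AVG_min),

with AVG/SD from the stimulated (max) and unstimulated (min) control groups
and n technical replicates; at n = 1 it is the classical Z′.  The √n reading
of the replicate correction is the standard-error interpretation: averaging n
replicate wells shrinks the effective 3σ bands.

A compound is a **hit** when the replicate-mean control-z of the size feature
is ≤ 0 (at or below the unstimulated median) at *any* tested dose.  Means are
taken over non-missing replicates with a floor of 2; compounds with no
evaluable dose are flagged unevaluable, never hits.

## Phenotype space and classification

Features enter the PCA when their Z′ between the forskolin-stimulated and
reference-inhibitor control conditions exceeds −1.0.  The cutoff is read as
"keep features separating better than Z′ = −1.0": the literal opposite would
discard every discriminating feature.  The gate is computed over cyst-level
observations of the two control conditions (with n = the technical replicate
count), which is what makes it sharp: a non-separating feature's group-mean
difference shrinks with the number of cysts while its SDs do not, driving
Z′ → −∞; at well level the same gate would leak ~3 % of pure-noise features
regardless of group size.  Ties in the ranking break alphabetically.

Selected features are standardized (they mix pixel areas, ratios and counts)
and decomposed into three principal components.  Signs follow a fixed
convention (largest-magnitude loading positive) so runs are deterministic.
Conditions are classified on replicate-mean scores against the control
centroids using a diagonal Mahalanobis distance with pooled within-control
scales: within radius 3.5 of the unstimulated centroid → `restored`; of the
stimulated centroid → `unchanged`; outside both → `novel`.  A condition
whose mean nuclei count falls below half the unstimulated median is `novel`
outright — the low-cell-count cytotoxicity flag — which also covers wells too
degraded to segment.  Both thresholds are configuration parameters; phenotype
clusters of this kind are conventionally judged by eye, so the defaults are
validated only against generator ground truth.

## Bliss synergy

Single-agent and combination sizes are scaled to effects in [0, 1]
(percent inhibition / 100, clamped), the independence prediction is
E = E_A + E_B − E_A·E_B, and each dose pair gets
CI = (E_A + E_B − E_A·E_B)/E_AB, undefined (flagged, not infinite) at
E_AB = 0.  CI below/above 1 ± 0.05 is synergistic/antagonistic, additive
inside the band; the band width is a default, since the underlying model only
declares >/< relations.  Effects are replicate means per dose pair.

## The synthetic screen generator

The generator emulates the *statistical structure* the analysis assumes, with
exhaustive ground truth:

* Cysts are spheres rendered per-plane as discs: a wall annulus
  (wall_intensity 3000, thickness 3 px) around a lumen (800) on background
  (200), 16-bit range, additive Gaussian noise (sd 40).  Anisotropic z is a
  configurable scale (15 xy-equivalent px per 50 µm plane step), so typical
  cysts intersect 1–3 planes.  Integrity < 1 removes arc segments of the
  wall (fragmented, toxic morphology).  Nuclei are Gaussian spots (σ = 2 px)
  spread around the wall with angular jitter, since nuclei are solid bodies
  that rarely coincide.
* Well radii are lognormal (median 10 px unstimulated, CV 0.2).  Forskolin
  multiplies radii by the swelling factor (1.6); a compound at concentration
  c suppresses that swelling by a Hill-curve fraction.  Toxic compounds
  additionally shrink radii, fragment walls and reduce nuclei counts with
  their own Hill dependence.
* **Basal inhibition.** Active compounds also shrink basal growth slightly
  (5 % of radius at full effect).  This reproduces the screen-level fact the
  size hit rule depends on: genuine actives land *at or below* the
  unstimulated median rather than exactly on it (a compound blocking
  cAMP-driven secretion also dampens basal growth).  With basal inhibition
  set to 0, a full-effect well is draw-for-draw identical to an unstimulated
  well on the same random substream — a property the tests exercise.
* Randomness: one master seed; layout, per-well cyst sampling, rendering and
  noise each use a substream keyed by (purpose, well index), so every well is
  independently reproducible and treatment effects are applied as multipliers
  *after* the treatment-independent draws.

Deliberately not modelled: optics (PSF, photobleaching, illumination
vignetting beyond an optional gradient), gel or debris background,
time-lapse, per-nucleus morphology.  Passing the recovery tests therefore
shows the analysis is correct and robust under the stated noise model — not
that it would survive arbitrary real-world artefacts (focus drift, well-edge
shading, autofluorescence).

## Problem sizes used in the shipped experiments

Tests and the acceptance script use desk-scale conditions: the 32-well
mini-screen (3 compounds × 2 doses × 4 replicates + 4/4 controls, 5 planes,
256 px images, 10–14 cysts per well — the full-plate geometry and effect
structure at ~10× fewer cysts), a 54-cyst noise-free scene (radii 5–35 px,
704 px, 14 planes, four vertically overlapping pairs) for segmentation
recovery, and 20-seed recovery ensembles.  Defaults in `ScreenConfig`
(384-well plate, 25 planes, 100–150 cysts/well, 1024 px) reflect the assay
as described rather than the desk scale.

## Known limitations

* Vertical linking assumes a cyst's discs overlap ≥ 50 % between adjacent
  planes; extreme anisotropy or very small spheres relative to the plane
  spacing can break a cyst into per-plane objects (the generator snaps small
  cysts to plane centres for the same reason real acquisitions focus on the
  object layer).
* Fragmented (low-integrity) rings cannot be hole-filled, so heavily toxic
  wells under-segment; the analysis treats the resulting empty/low-count
  wells as signal (unevaluable for size, `novel` via the nuclei flag), not
  as missingness to be imputed.
* The classification thresholds (Mahalanobis radius, nuclei fraction) are
  fixture-validated defaults, not biologically calibrated constants.
* Multi-plate screens are supported by the `plate` column, but no
  inter-plate batch correction beyond per-plate normalization is attempted.
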