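# Methods

## Problem setting

High-LET ion irradiation produces clustered DNA double-strand breaks along
particle trajectories. In uranyl-acetate-contrasted ultrathin sections imaged
by TEM, the affected chromatin decondenses into electron-lucent low electron
density domains (LEDDs), and immunogold labels (6 nm and 10 nm colloidal
gold conjugates against repair factors) appear as small, very dark, circular
beads. The analysis quantifies where those beads and their clusters sit
relative to LEDD boundaries and to the heterochromatin/euchromatin
partition. Because no micrographs are publicly deposited, the package ships
a synthetic-scene generator with exact ground truth; every stage is
validated against it.

## Image model and preprocessing

A micrograph is a single-channel intensity array normalized to [0, 1] with a
user-supplied nm/px calibration (never inferred; acquisition pixel pitch is
an instrument setting). RGB inputs are collapsed by Rec. 601 luminance.
Brightness/contrast adjustment is the common editor semantics — linear gain
`v·(1+b/100)` followed by midpoint-pivot stretch
`(v−0.5)(1+c/100)+0.5`, clipped — with defaults +50%/+80%, the uniform
enhancement applied to real micrographs before automatic annotation. The
transform is monotone, so the quantile-based detector below is insensitive
to it; synthetic scenes are rendered at analysis-ready contrast and are
therefore analyzed with the identity setting (0/0) to avoid pointless
saturation of the already well-separated gray levels. Artifacts, the
nucleolus and other non-relevant areas are removed by polygonal exclusion
masks; excluded pixels never enter any statistic and particles centered on
them are dropped (with a logged count).

## Bead detection

The original workflow used a proprietary trained classifier; `ledscan`
replaces it with a deterministic pipeline driven by the same cues — size,
shape, density:

1. **Background flattening.** The residual `image − closing(image)` (grayscale
   closing with a ~41 px square element, i.e. a rolling-ball background for
   dark features) is ~0 everywhere except in dark valleys narrower than the
   element. This equalizes bead contrast across heterochromatin, euchromatin
   and bright LEDD interiors, and makes the next step exactly invariant to
   additive intensity shifts.
2. **Quantile thresholding.** Pixels with residual strictly below the 2%
   in-mask quantile are candidate bead pixels. The strict inequality keeps
   flat regions sitting exactly at the quantile value (e.g. noise-free
   backgrounds) out of the mask.
3. **Splitting.** Touching beads are separated by watershed on the distance
   transform, with markers at local maxima separated by ≥ 5 nm.
4. **Measurement.** Each object's depth is measured on the smoothed residual
   relative to a local annulus baseline (the baseline correction removes the
   noise-envelope bias of the closing). The object footprint is the connected
   half-depth level set; its equivalent radius is converted to a pre-blur
   bead radius by inverting a numerically computed disc⊗Gaussian calibration
   at the assumed PSF width (`psf_sigma_nm`, default 2 nm). The reported
   `equivalent_diameter_nm` is the diameter of the circle matching that
   estimated footprint.
5. **Filters.** Circularity `4πA/P²` (Crofton perimeter) of the half-depth
   level set must exceed 0.6; the object core (mean of its darkest third)
   must be darker than the local background annulus by ≥ 0.1; and the object
   must satisfy a *density* criterion: either its core is darker than the
   heterochromatin reference level (the 5% quantile of the smoothed image)
   by ≥ 0.05, or its residual depth exceeds anything chromatin contrast
   alone can produce (1.5× the gap between the median and the dark
   reference). The second branch keeps 6 nm beads inside bright LEDDs; the
   first branch rejects small dark heterochromatin islands, whose cores sit
   at heterochromatin level. Both references are quantiles, so the criterion
   is shift-invariant.
6. **Classification.** A diameter is assigned to the 6 nm or 10 nm class by
   minimal relative deviation `|d − nominal|/nominal` (equal-deviation point
   7.5 nm) and rejected outside both ±40% windows.

On noise-free synthetics detection is exact (precision = recall = 1, no
class confusion at n = 200); at the generator's realistic degradation
(σ = 0.03, PSF 2 nm) pooled precision ≈ 0.99, recall ≈ 0.96, class accuracy
≈ 0.98 over 560 beads. Residual misses are mostly 6 nm beads in tight
multi-bead clusters.

## Chromatin classification and LEDD segmentation

Bead pixels are in-filled with a local rank median (radius 15 nm) so gold
does not masquerade as heterochromatin; the image is then median-smoothed at
the 30 nm chromatin texture scale and split into three classes by maximal
between-class variance (multi-Otsu) over in-mask pixels, assigned by
intensity order: dark → heterochromatin, mid → euchromatin, bright → LEDD.
Thresholds are recomputed per image and never hand-edited, honoring the
constraint that LEDD-determining thresholds must not be tuned per
micrograph.

Two degeneracy guards handle sections without three genuine gray levels: a
uniform image raises a segmentation error, and a *bimodal* image — an
unirradiated section with heterochromatin and euchromatin only, where the
three-class split would place its middle class on the boundary ramp — is
detected by a vanishing middle class (< 10% of pixels) and re-labeled as
het/eu with no LEDD. A bright class whose separation from the middle class
is < 0.5× the het–eu gap is likewise merged back into euchromatin. These
rules assume nuclear sections always contain both chromatin phases, which
holds for the tissue in question.

LEDD segmentation takes the bright class, applies Euclidean-disk closing
(50 nm) and hole filling, discards components below 0.05 µm², and reports
per-region areas (`pixel count × scale² × 10⁻⁶` µm²) and marching-squares
boundary polygons. Group summaries report the mean of per-section mean
areas with SE over sections.

## Spatial statistics

The signed distance to the nearest LEDD boundary is the Euclidean distance
transform of the LEDD union, negative inside. Zones are a pure function of
that distance: inside (d < −300 nm), border (|d| ≤ 300 nm, closed at the
tie), outside. The single ±300 nm border band follows the three reported
zone categories; the finer outside profile uses left-open, right-closed
bands (0,100], (100,200], (200,300], (300,400] nm matching the printed
integer labels. With several LEDDs the distance is to the nearest boundary,
so overlapping border bands merge without double counting; with zero LEDDs
all pixels are outside at +∞ and the partition is flagged.

Clusters are single-linkage components of the graph joining bead centers
within 50 nm — the span of two beads bridged by primary+secondary antibody
stacks; the linkage is a parameter. Categories are 1–2, 3–4, >4 beads per
cluster; clusters with ≥ 3 beads count as clustered lesions for the zone
percentages (the comparator is configurable). Cluster ids are the minimum
member particle id; a brute-force transitive closure over the pairwise
distance matrix serves as the independent oracle in tests. Band densities
divide per-band bead counts by per-band pixel areas (µm²); the kernel
density heatmap is a Gaussian-smoothed histogram rescaled to integrate to
the bead count. Summaries across sections report mean ± SE (sd/√n) per
condition × time point.

## Synthetic scenes

The generator renders, in order: a two-phase chromatin texture (smoothed
Gaussian random field thresholded to the requested heterochromatin fraction,
correlation scale 80 nm), elliptical LEDDs (default two per field, radii
300–450 nm, emulating section-plane cuts through track-associated domains),
and anti-aliased bead discs with ≤10% diameter jitter, followed by Gaussian
PSF blur (σ = 2 nm) and additive Gaussian noise (σ = 0.03). Gray means are
bead 0.05 < heterochromatin 0.35 < euchromatin 0.55 < LEDD 0.80 — declared,
reproducible defaults (the grayscale levels of the original workflow are
not published). Scene texture, bead placement and noise use three
independent RNG streams derived from one seed, so the same seed yields the
identical scene with or without beads.

Bead placement is cluster-based: cluster sizes are drawn from a distribution
over {1,…,5} (default mass 0.80 on two-bead pairs, reflecting paired
labeling of single break ends) until the requested per-class count is
reached exactly; members scatter within a 40 nm disc so the default 50 nm
linkage reconnects them. Cluster anchors follow either a uniform law or a
boundary-decay law: a distance is drawn from Exp(L) (default L = 150 nm, the
simplest monotone family for a density that decreases with distance from
the LEDD) and an anchor pixel is chosen uniformly among pixels at that
rounded |signed distance|, inside or outside. When a
heterochromatin:euchromatin placement ratio is requested, the target class
is drawn from the ratio and candidates are restricted to that class eroded
by 15 nm, making the generating class unambiguous ground truth. Beads never
overlap; 100 failed attempts per cluster raise a generation error.

What the generator does *not* emulate: physical TEM image formation
(multislice/CTF), 3-D section geometry, stain granularity, knife marks, or
organelles other than chromatin phases. Passing tests therefore demonstrate
correctness of the measurement chain under the stated statistical model,
not performance on arbitrary real micrographs.

## Validation strategy and problem sizes

The acceptance suite validates: the closed-form dose reconstruction
(1.602×10⁻⁹ · 190 · 5×10⁶ = 1.52 Gy); Poisson fluence–track consistency
(mean 5.00 tracks per 100 µm² nucleus, 50,000 nuclei, 3 SE); oracle
equivalence of clustering (50 random instances, n ≤ 300) and of the signed
distance field (per-pixel brute force at 256²); detection ground-truth
recovery (200 noise-free and 560 noisy beads over fixed seeds); segmentation
accuracy (500 nm disc area within 3%, three-tone pixel agreement ≥ 99%,
exact area conservation); and full-pipeline parameter recovery on a
25-section dataset (1536² px at 1 nm/px, 80 beads/section, two LEDDs).

For parameter recovery, estimates are compared with the dataset's *realized*
generating values within 2 SE across sections: the mean |boundary distance|
against the ground-truth mean (the realized exponential is slightly
truncated by the finite field, so the realized mean — not the nominal L —
is the recoverable quantity; the nominal 150 nm is separately recovered to
within 15% from pure ground truth at n = 2000), the heterochromatin placement
fraction against the realized fraction, and cluster-size categories against
the categories of ground-truth bead positions clustered *under the same
50 nm linkage*. The last choice reflects an identifiability limit, not a
shortcut: at realistic bead densities near LEDD borders, independently
generated clusters legitimately coalesce under single linkage, so the
generative cluster partition is not recoverable from positions by any
method — the observable is the linkage partition, and detection must (and
does) reproduce it.

## Numerical choices and conventions

- Coordinates: 0-based (row, col) pixel indices; physical nm = index ×
  scale at pixel centers; x = col, y = row.
- Band and zone ties: border is closed at |d| = 300 nm; bands are
  left-open/right-closed.
- Cluster chromatin class: majority vote of member centroid labels, ties to
  the denser (darker) class.
- Empty results are flagged, not raised: zero LEDDs, zero qualifying
  clusters, empty groups.
- Serialization: particle tables as CSV (positions to 0.01 nm), LEDD
  polygons and provenance as JSON; annotation round trips are validated
  against image bounds on read.
- Determinism: every stochastic component takes an explicit seed;
  per-section seeds derive from a master seed via `SeedSequence`; pipeline
  reruns are byte-identical.

## Known limitations

- The detector assumes a single dominant PSF width; strong defocus or
  astigmatism would bias size classes toward 10 nm.
- The chromatin bimodality guard assumes heterochromatin is present; a
  hypothetical section with euchromatin and LEDDs only would be mislabeled.
- Size classification degrades when beads overlap within < ~6 nm
  center-to-center; such pairs are physically near-touching and partially
  unresolvable at the rendered PSF.
- The traversal simulator treats nuclei as independent discs of fixed area;
  no cell-cycle or geometry variability is modeled.
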