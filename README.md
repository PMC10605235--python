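# ledscan

Automated analysis of immunogold-labeled transmission electron micrographs of
irradiated cell nuclei.

After high-LET irradiation (e.g. carbon ions at LET 190 keV/µm), chromatin
decondenses along particle trajectories into electron-lucent regions — low
electron density domains (LEDDs) — while DNA double-strand-break repair
factors, labeled with 6 nm and 10 nm colloidal gold, appear as small, dark,
circular beads. `ledscan` turns calibrated TEM micrographs (or ground-truthed
synthetic ones) into quantitative spatial statistics:

- **Bead detection and sizing** — rolling-ball (grayscale closing) background
  removal, quantile thresholding, watershed splitting of touching beads, and
  PSF-aware size estimation that assigns each bead to the 6 nm or 10 nm class
  by minimal relative deviation.
- **Chromatin classification** — three-class maximal between-class-variance
  thresholding of the median-smoothed image into heterochromatin (dark),
  euchromatin (mid) and LEDD (bright), with bead pixels in-filled first.
- **LEDD segmentation** — morphological closing, hole filling and a minimum
  area filter; areas in µm², marching-squares boundary polygons.
- **Spatial statistics** — signed Euclidean distance to the nearest LEDD
  boundary; inside / border (±300 nm) / outside zones; finer outside bands
  (0,100], (100,200], (200,300], (300,400] nm; single-linkage bead clusters
  (50 nm) in size categories 1–2 / 3–4 / >4; band density profiles
  (particles/µm²) and Gaussian kernel density heatmaps.
- **Dosimetry** — `D[Gy] = 1.602e-9 · LET[keV/µm] · Φ[cm⁻²] / ρ[g/cm³]` and a
  Poisson traversal simulator (mean `Φ·A` tracks through a nucleus of
  cross-section `A`).
- **Synthetic micrographs** — a generator that renders two-phase chromatin
  texture, elliptical LEDDs, and anti-aliased gold beads placed uniformly or
  with exponentially decaying density from the LEDD boundary, returning exact
  ground truth for every bead and pixel.

## Worked example

```python
import ledscan as ls

# a synthetic nuclear section: 1.536 µm field at 1 nm/px, two LEDDs,
# 40 + 40 beads placed with a 150 nm boundary-decay profile
img, truth = ls.generate_micrograph(ls.SceneSpec(seed=42))

dets = ls.detect_particles(img)
m = ls.match_to_ground_truth(dets, truth.particles)
print(len(dets), round(m.precision, 3), round(m.recall, 3))
# 77 1.0 0.963

cmap = ls.classify_chromatin(img)
ledds = ls.segment_ledds(cmap, img)
part = ls.build_partition(ledds, img.shape, img.scale_nm_per_px,
                          analysis_mask=img.analysis_mask())
table = ls.build_spatial_table(dets, part, cmap)
print({k: round(v, 1) for k, v in table.zone_percentages.items() if k != "empty"})
# {'inside': 0.0, 'border': 100.0, 'outside': 0.0, 'n_clusters': 8}
print(table.band_profile[["band", "count", "density_per_um2"]].round(1).to_string(index=False))
#       band  count  density_per_um2
#   1-100 nm     22             75.7
# 101-200 nm     10             28.3
# 201-300 nm      6             14.7
# 301-400 nm      4             11.2
```

77 of 80 beads are recovered with no false positives at this seed's noise
level; every cluster with ≥3 beads sits in the ±300 nm border zone, and the
bead density falls monotonically with distance from the LEDD boundary — the
spatial signature the analysis is designed to measure.

The same pipeline runs from the shell:

```bash
ledscan dose --let 190 --fluence 5e6          # -> 1.52 Gy
ledscan simulate-tracks --area 100 --n 50000 --seed 7
ledscan detect image.tif --scale-nm 1.0 --out particles.csv
ledscan segment image.tif --scale-nm 1.0 --out ledds.json
ledscan run --config run.yaml                 # all stages, one output dir
```

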