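# tautrace

A tested, reusable pipeline linking cellular tau pathology to in vivo tau-PET
signal, exercised end to end on synthetic data with attached ground truth:

| module | what it does |
| --- | --- |
| `tautrace.synthetic_data` | Seeded generators: AT8 stain sections with class-specific morphologies (NFT/CB vs TA/TF), coupled autoradiography rasters, one-tissue-compartment dynamic PET (curves and 4-D phantoms), single-cell radiotracing cohorts, cortical slabs with depth-dependent binding |
| `tautrace.ihc_morphometry` | Segmentation of AT8-positive objects, shape/intensity descriptors, exemplar-calibrated interval rules, NFT/CB vs TA/TF channel classification, per-ROI occupancy and colocalization |
| `tautrace.autorad_quant` | Subfield/reference binding ratios; pooled and per-subject correlations, partial correlation with region cofactors, two-predictor standardized regression, intensity-vs-occupancy contrasts |
| `tautrace.kinetics` | Logan graphical analysis with image-derived input functions (10% maximum-error t* search, VT floor 0), voxelwise VT maps, static-window SUVR (default 20–40 min), Cohen's d, voxelwise regression with p < 0.005 / k > 20 cluster filtering |
| `tautrace.scrad` | Decay correction (F-18, 109.77 min), per-cell uptake, %ID*BW, ≥2-fold signal-to-background QC, pellet purity, and the cell-census extrapolation (71×10⁶ neurons / 21×10⁶ astrocytes) against PET increments |
| `tautrace.cortical_layers` | Five sampling surfaces from GM/CSF to below the GM/WM boundary, per-parcel SUVR profiles (default 200 parcels), repeated-measures ANOVA with Tukey-adjusted contrasts, per-layer group effect sizes |

## CLI

```bash
ihc-quant --image at8.tif --rois rois.geojson --rules rules.json --out table.csv
arg-quant ratios --arg arg.tif --rois rois.geojson --reference-id ref --out ratios.csv
arg-quant correlate --table joined.csv --mode pooled --out results.json
kinetics fit-logan --tac tac.csv --input input.csv
kinetics vt-image --pet dyn.nii --frames frames.json --input-mask carotid.nii --out vt.nii
kinetics suvr --pet dyn.nii --frames frames.json --ref-mask ref.nii --out suvr.nii
scrad run --pellets pellets.csv --pet increments.csv --out scrad
layers sample --pet pet.nii --labels labels.nii --parcels parcels.nii --out profiles.csv
layers compare --profiles profiles.csv --out compare.json
```

File conventions: single-channel 16-bit TIFF for stain rasters (pixel size in
the image description), NIfTI-1 for volumes with frame schedules in sidecar
JSON, GeoJSON ROI polygons in pixel coordinates (x = column, y = row), CSV
tables. See `tautrace.io` for readers/writers.

## Conventions worth knowing

- One global seed fans out to per-stage child generators via
  `SeedSequence.spawn`; identical seeds give bit-identical outputs.
- 8-connectivity for image components; a pixel belongs to an ROI iff its
  center (x = col, y = row, origin top-left) falls inside the polygon.
- Perimeter is the classical weighted contour-length estimator, floored at the
  equivalent-circle perimeter for few-pixel specks; circularity `4πA/P²`,
  roundness `4A/(π·major²)`, compactness `√(4A/π)/major`.
- Logan integrals are trapezoidal on frame mid-times with an implicit (0, 0)
  origin; t* is the earliest mid-time whose segment satisfies the maximum
  relative error bound.
- Undefined correlations propagate as NaN, never as 0; two-sided p-values
  throughout, no multiple-testing correction.
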