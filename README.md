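# wmh-morph

Quantitative morphometry of white-matter hyperintensity (WMH) lesions on
T2-FLAIR MRI: shape, texture, and a potential growth index.

WMH burden in aging brains is usually summarized as a total lesion volume,
which ignores lesion morphology entirely. `wmh-morph` characterizes each
segmented lesion by

- **shape** — the lesion mask is rescaled to a canonical 60 × 60 canvas and
  expanded in Zernike polynomials on the unit disc; the magnitudes
  |Z_nm| of the complex coefficients up to order n = 5 (12 distinct values,
  since |Z_{n,−m}| = |Z_{n,+m}|) form a rotation-invariant shape feature
  vector;
- **texture** — 2D lesion components are linked across adjacent slices into
  3D lesions ("WMH3D"), despiked at mean ± 3 SD, min–max normalized by the
  lesion's intensity extremes (gMin, gMax), and summarized by a fuzzy
  histogram in which each normalized intensity s splits its unit mass
  linearly between the two nearest of n = 5 bins;
- **potential growth** — from the lesion's boundary voxels, a region-growing
  pass over 8-neighborhoods collects non-lesion voxels p with
  gMax − f(p) < γ·(gMax − gMin) (γ = 1.02): the penumbra of tissue whose
  signal already resembles the lesion. With l = 3 one-voxel-thick
  4-connected rings E_i around the mask and weights w_i = i / Σj, the
  potential growth index is P_g = Σ_i GV_i·w_i / V_l ∈ [0, 1], where GV_i
  counts growth voxels in ring i and V_l is the total ring size.

Lesions are grouped by K-means (Euclidean distance for shape features,
Manhattan for texture histograms), with the number of clusters selected by
the gap statistic (Tibshirani's uniform-reference method; N = 20 candidate
cluster counts, B = 10 reference datasets). A closing one-way ANOVA tests
whether P_g differs across shape and texture clusters, repeated over 1,000
re-seeded K-means trials to report the range of P values.

Real FLAIR volumes are not bundled; `wmh_morph.synthetic_fixtures`
generates study volumes with known ground truth (shape families, penumbral
edge profiles, planted feature clusters) on which every stage is tested.

## Worked example

```python
from wmh_morph import pipeline, synthetic_fixtures as synth

demo = synth.make_demo_volume(seed=0)          # 18 lesions, 3 shape families
cfg = pipeline.RunConfig(master_seed=1, trials=100)
report = pipeline.run(demo.volume, demo.probability_map, cfg, out_dir="report")

print(len(report.components), len(report.lesions3d))
print(report.shape_gap.k_opt, report.texture_gap.k_opt)
print(report.pgi_df["p_g"].min(), round(report.pgi_df["p_g"].mean(), 4),
      round(report.pgi_df["p_g"].max(), 4))
```

prints

```
54 18
7 6
0.0 0.0289 0.0916
```

54 two-dimensional lesion images (each of the 18 lesions spans 3 slices),
gap-statistic cluster counts of 7 for shape and 6 for texture, and
per-lesion growth indices between 0 (step-edged lesions: nothing around
the boundary resembles lesion tissue) and ≈ 0.09 (lesions with shallow
penumbral ramps). The `report/` directory receives per-lesion CSVs
(features, clusters, PGI), gap curves, and the ANOVA summary as JSON.

The same pipeline is available from a shell:

```sh
wmh-morph simulate --out study --seed 0
wmh-morph run --volume study/volume.nii.gz --mask study/probability_map.nii.gz --out report
```

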