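# adiffi

Voxel-wise spatial-signature analysis of brain-tumor cohorts in atlas
space: lesion frequency and differential maps, laterality statistics, and
the **analysis of differential involvement (ADIFFI)** — a voxel-wise
two-sided Fisher's exact test between two patient groups with
family-wise-error control by a max-statistic permutation null over
suprathreshold cluster extents.

Because real patient images of this kind are rarely shareable, the package
ships a first-class **synthetic cohort generator**: nested-sphere tumor
segmentations (necrosis ⊂ enhancing ⊂ edema) on a shared grid, with
configurable group sizes, volume model, and an optional *planted* spatial
effect whose ground-truth region lets you score recovery (Dice) and
calibrate family-wise error.

## Layout

| module | contents |
|---|---|
| `adiffi.synthetic` | cohort spec, nested-sphere rasterizer, planted effects, label permutation |
| `adiffi.io` | NIfTI/CSV cohort I/O, label dialects, compartment derivation (whole tumor / tumor core / non-enhancing) |
| `adiffi.volumetrics` | volumes in cm³, Kruskal–Wallis / Mann–Whitney comparisons, center-of-mass laterality and chi-square tests |
| `adiffi.frequency` | per-voxel frequency maps `F(v) = counts/n × 100`, differentials, threshold summaries |
| `adiffi.inference` | scalar/lookup Fisher exact test, 3D suprathreshold clustering (6/18/26-connectivity), permutation null, full ADIFFI |
| `adiffi.pipeline` / `adiffi.cli` | end-to-end orchestration, manifest, `adiffi` console command |

## CLI

```bash
# synthetic cohort: 227 patients, subtype sizes 85/69/54/19, ~90-105 cm³ lesions
adiffi simulate --out demo --seed 7

# one comparison cell at full settings
adiffi run --cohort demo/cohort.csv --group-by subtype --groups MES,RTK_I \
           --compartment non_enhancing --raw-p 0.005 --permutations 500 \
           --connectivity 26 --alpha 0.05 --seed 7 --out demo_run

# headline numbers of a completed run
adiffi report --manifest demo_run/manifest.json
```

`adiffi run --config run.yaml` drives a full multi-comparison analysis
(all subtype pairs × all compartments by default); every artifact —
frequency/differential/p-value NIfTIs, cluster CSVs, summary tables — is
recorded in `manifest.json` together with the config hash and seed, so a
completed run is fully reproducible.

### Statistical conventions

* Hemisphere goodness of fit vs. 50/50: 1-df chi-square **without**
  continuity correction. Contingency tests: Yates correction for 2×2
  tables only. Centers of mass exactly on the midline (world plane
  x = 0 by default) are excluded from laterality counts.
* Fisher's exact test is two-sided (point probabilities ≤ observed,
  relative tolerance 1e-7); a `(n1+1)×(n2+1)` lookup table makes the
  voxel-wise map a single indexing pass.
* Cluster-forming threshold is a strict `p < raw_p_threshold`; the
  minimum significant cluster size is the smallest `k` with
  `#(null max sizes ≥ k)/n_permutations < alpha`. The observed labeling
  is not pooled into the null; a rank-based corrected p for the largest
  observed cluster is reported alongside.
* Each permutation uses the substream `default_rng([seed, index])`, so
  results are independent of execution order.

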