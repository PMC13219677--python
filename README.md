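# ablaq — quantitative 3D analysis of lung microwave-ablation zones

Lung microwave ablation (LMWA) destroys a tumor by heating tissue around an
inserted antenna.  Operators plan treatments with a vendor table of expected
ellipsoidal ablation dimensions per (power, duration) setting, but actual
ablation zones — segmented on the one-month follow-up CT — vary widely in
volume and diverge from ellipsoids.  `ablaq` is a toolkit for interventional
radiology researchers to quantify that variability:

* **Applicator-centric coordinate system (ACCS).**  Every zone is resampled
  into a 64 × 64 × 64 mm grid (1 mm isotropic) centred at the applicator tip
  with the third axis along the insertion direction, so zones from different
  patients are directly comparable.  Length, slice-wise caliper diameters
  and areas, maximum width, tip-to-front-edge distance and the front/back
  asymmetry are all measured in this frame.
* **Shape statistics.**  Volume V, marching-cubes surface area A,
  sphericity π^(1/3)(6V)^(2/3)/A, elongation √(λ₁/λ₂) of the principal-axis
  eigenvalues (≥ 1), and surface-to-volume ratio A/V.
* **Topological shape space.**  Each mask becomes a dual cubical complex;
  the Euler characteristic transform (ECT) records, for 256 directions × 64
  height thresholds, χ(t) = V − E + F − C of the sublevel complex — a
  1 × 16,384 shape signature needing no point correspondence.  Kernel PCA
  under an ANOVA kernel K(x,y) = (Σᵢ e^{−σ(xᵢ−yᵢ)²})^d embeds the cohort;
  vendor ellipsoids are projected into the same space.
* **Vendor model comparison.**  Bilinear interpolation of the vendor table,
  synthesis of the predicted prolate ellipsoid in the ACCS, per-metric log
  discrepancies ln(observed/vendor), and a random-intercept linear mixed
  model of the discrepancy on tissue contraction, follow-up interval,
  log energy and log tumor volume (exponentiated coefficients).
* **Tissue contraction.**  From 3–10 anatomical landmarks matched between
  pre-procedure and follow-up CT: contraction = mean decrease of all
  pairwise landmark distances (rigid-motion invariant, no registration).
* **Cluster-aware statistics.**  Patients contribute 1–3 ablations, so
  paired comparisons use a clustered Wilcoxon signed-rank test
  (Rosner–Glynn–Lee-style cluster-sum variance, Z = Σsᵢ / √Σ_c(Σ_{i∈c}sᵢ)²),
  correlations use a patient-level cluster bootstrap, and p-values are
  Holm-adjusted.
* **Synthetic cohorts.**  No public dataset carries masks + applicator
  geometry + landmarks, so a seeded generator emulates the cohort structure
  (patient clustering, 65 W settings, lognormal volumes, front-narrower
  egg-shaped lobulated zones, contraction encoded in landmark displacement)
  with every generating parameter saved to a truth table.

## Worked example

Generate one synthetic ablation at 65 W / 5 min and measure it:

```python
import numpy as np
from ablaq import (CohortSpec, simulate_records, simulate_ablation_mask,
                   measure_ablation, interpolate_vendor, default_vendor_table,
                   discrepancy_ratio)

spec = CohortSpec(n_patients=1, setting_weights={(65.0, 5.0): 1.0})
rng = np.random.default_rng(42)
rec = simulate_records(spec, rng).iloc[0]
mask, applicator, truth = simulate_ablation_mask(spec, rec, rng)

metrics, accs = measure_ablation(mask, applicator)
pred = interpolate_vendor(default_vendor_table(), 65, 5)
print(metrics["length_mm"], metrics["max_width_mm"], metrics["tip_to_edge_mm"])
# 34.0 20.843 5.0
print(pred.length_mm, pred.width_mm, pred.tip_to_edge_mm)
# 35.0 18.5 4.0
print(round(discrepancy_ratio(metrics["volume_cm3"], pred.volume_cm3), 3))
# -0.144
```

The measured zone is 34 mm long with a 20.8 mm maximum caliper width and
extends 5 mm past the applicator tip; the vendor predicts a 35 × 18.5 mm
ellipsoid ending 4 mm past the tip.  The log volume discrepancy −0.144
means the zone's volume is ~13% below the vendor prediction.  Note the
front half (18.3 mm max width) is narrower than the back (20.8 mm) — the
generator reproduces the front-narrower asymmetry real zones show.

The same pipeline runs from the shell:

```bash
ablaq simulate --out cohort/ --seed 17           # masks, markups, manifest, truth
ablaq cohort --manifest cohort/manifest.csv --out report/ --seed 17
ablaq measure --mask zone.nii.gz --applicator probe.fcsv
ablaq vendor --power 65 --duration 5
ablaq contraction --pre pre.fcsv --post post.fcsv
ablaq ect --masks cohort/manifest.csv --out ect.csv
```

`ablaq cohort` writes per-ablation `metrics.csv`, the observed-vs-vendor
comparison table (`table2.csv`), per-setting distribution summaries
(`table3.csv`), the mixed-model effect table (`table4.csv`),
shape-space coordinates (`shape_space.csv`) and a `metadata.json` of
conventions.

## Conventions worth knowing

* World coordinates are used exactly as the mask header and markup files
  declare them; **no RAS/LPS conversion is attempted** — masks and markups
  must share one world frame.
* Elongation is reported ≥ 1 (major/second axis); the reciprocal radiomics
  convention is emitted alongside.
* Kurtosis is Pearson (normal = 3).  "Mean absolute deviation" is about the
  mean.
* The packaged vendor table contains only the four published 65 W rows
  (2, 4, 5, 6 min); supply a full table as CSV
  (`power_w,duration_min,length_mm,width_mm,tip_to_edge_mm,volume_cm3`)
  for other settings.  Vendor volumes are reported as given, never
  recomputed from the axes.

See `docs/methods.md` for the full model description, parameter defaults
and known limitations.
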