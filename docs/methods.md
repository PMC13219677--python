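# Methods

This note records the models, conventions, numerical choices and
limitations behind `ablaq`.  Nothing here states an empirical result the
test suite or `scripts/acceptance.py` does not itself compute.

## Applicator-centric coordinate system (ACCS)

Ablation zones are resampled from their native CT grid into a tip-centred
frame before any measurement, so cohort metrics are independent of
acquisition spacing and patient orientation.

* Grid: 64 × 64 × 64 voxels, 1 mm isotropic; the applicator tip sits at the
  centre voxel (32, 32, 32), so slice k lies (k − 32) mm from the tip along
  the insertion axis and positive offsets are distal ("front").
* The frame's third axis is the insertion direction.  The residual spin
  about that axis is fixed by aligning the first transverse axis with the
  projection of world x̂ (ŷ when the applicator is within ~1e−6 of x̂).
  Axial measurements are spin-invariant by construction; the ECT embedding
  is not, and inherits this convention.
* Resampling is nearest-neighbour (labels stay binary).  Foreground
  touching any grid face sets a truncation flag and logs a warning rather
  than failing: a 64 mm cube clips the proximal end of the longest zones
  (length can exceed 38 mm with tip offsets of ~6 mm), exactly as a fixed
  common frame must.
* Native grids may be anisotropic; the synthetic generator deliberately
  writes masks at (0.8, 0.8, 1.25) mm to exercise this path.  Thin-slice
  chest CT is typically reconstructed at 1.25 mm slices; in-plane spacing
  varies, and all measurements are made after resampling regardless.

### Axial measurements

Per 1-mm slice perpendicular to the axis: area = foreground voxel count ×
1 mm², and rotating-caliper (Feret) diameters at 90 equally spaced angles
over [0, π).  The caliper width at angle θ is the extent of the projected
pixel centres plus a fixed 1 mm footprint: a single pixel measures 1 mm at
every angle, and widths are monotone under dilation.  (The alternative —
projecting the full pixel squares — makes a single pixel measure up to
√2 mm diagonally; we prefer the fixed-footprint form for its simple
single-voxel convention.)  Mean, median and max of the 90 widths are all
recorded; the mean is the default "slice diameter", with the others
exposed because results are insensitive to the choice.

* Length: inclusive occupied extent, (last − first + 1) mm; internal empty
  slices are ignored; a single-slice object has length 1 mm.
* Tip-to-front-edge: the largest occupied offset (how far the zone extends
  past the tip).
* Front/back split: at the midpoint of the occupied extent; slices strictly
  distal to the midpoint are "front", the rest (including the mid-slice on
  ties) are "back".  Front and back maximum widths/areas feed the asymmetry
  test.

## Shape statistics

Computed on the ACCS grid for internal consistency:

* Volume = voxel count × 1 mm³.
* Surface area: marching-cubes iso-surface at 0.5 after Gaussian smoothing
  of the binary field with σ = 0.7 voxels.  Raw binary marching cubes
  carries staircase facets that inflate a digital ball's area by ~9%
  (sphericity ~0.92); with this regularisation balls of radius ≥ 8 voxels
  measure within ~1% of the analytic value.  Objects a few voxels across
  can overshoot slightly; if smoothing pushes a tiny object entirely under
  the iso-level the raw binary field is meshed instead.
* Sphericity = π^(1/3)(6V)^(2/3)/A ∈ (0, ~1].
* Elongation = √(λ₁/λ₂), λ₁ ≥ λ₂ ≥ λ₃ the eigenvalues of the foreground
  voxel-centre covariance: the ratio of the two largest principal axis
  lengths, ≥ 1.  The common radiomics convention is the reciprocal (≤ 1);
  both are emitted, the ≥ 1 form is primary.  A single-voxel (or collinear)
  mask has no defined second axis; elongation is reported as 1 with a
  warning.

## Vendor model

The vendor table maps (power W, duration min) to expected ellipsoid
dimensions.  Only four rows are public (65 W × {2, 4, 5, 6} min); they ship
as the default fixture, and a complete table can be supplied as CSV.
Interpolation is bilinear per metric, exact at grid nodes and monotone
between nodes for monotone tables; queries outside 35–65 W / 1–10 min (or
outside the supplied table's node range) raise unless an explicit
extrapolation flag clamps them to the nearest supported setting — the route
taken for the occasional low-power (20 W) ablation.

The predicted ellipsoid is synthesized as a prolate body (two equal
transverse axes — the vendor interface is assumed to report one width):
long semi-axis length/2 along the applicator axis, transverse semi-axes
width/2, distal pole anchored tip-to-edge mm past the tip.  Published
vendor volumes disagree with the prolate closed form πLW²/6 by ~5–8%, so
the vendor's volume is always reported as given and never recomputed from
the axes; synthesized ellipsoids serve only shape-space projection and
geometry round-trips (which recover the three dimensions within 1 voxel
for every fixture row).

Discrepancy per metric is ln(observed/vendor).

## Euler characteristic transform

The dual cubical complex of a mask has one vertex per foreground voxel (at
the voxel centre), an edge per face-adjacent pair, a square per 2×2
foreground block in an axis plane, and a cube per 2×2×2 block.  The
construction detail is a genuine design choice (voxel-as-cube is the main
alternative); the vertex-per-voxel form is validated against brute-force
cell enumeration, not against any external encoding.

For a unit direction v, vertex height = ⟨position, v⟩ and a cell's
filtration value is the maximum over its vertices (lower-star); because
heights are linear this equals the base vertex height plus the positive
parts of v's components along the spanned axes, which is what the
vectorised engine uses.  Sublevel counting uses ≤ (with a 1e−12 guard
against float ties); curves are piecewise constant and right-continuous,
and the final sample of a complete filtration equals χ of the whole
complex (1 for any contractible solid).

Defaults: 256 directions from a deterministic Fibonacci sphere lattice
(reproducibility beats i.i.d. sampling; the count is the only thing
specified by convention) × 64 thresholds evenly spaced over ±32√3 mm — the
ACCS circumscribed radius, identical for every shape so vectors share one
feature space.  Shapes are encoded tip-centred and applicator-aligned (no
centroid centering): axial position, e.g. the tip offset, is deliberately
part of the signature.

### Shape space

ANOVA kernel K(x, y) = (Σᵢ exp(−σ(xᵢ−yᵢ)²))^degree with degree 1 and
σ = 1/(median per-feature variance of the fitted set) by default (falling
back to the mean variance when the median is zero — thresholds below every
shape's support give constant features).  Kernel PCA uses standard double
centering and an eigendecomposition; out-of-sample projection centres new
kernel rows with the fitted set's row/grand means, so projecting a fitted
shape reproduces its score exactly.  The implementation is cross-checked
against scikit-learn's KernelPCA on a precomputed kernel in the tests.

## Tissue contraction

Pairwise Euclidean distances among 3–10 labelled landmarks are computed in
the pre-procedure and follow-up scans (label-sorted pair order);
contraction = mean(d_pre − d_post), positive for shrinkage.  The statistic
is invariant to rigid motion between scans — the reason a distance-based
definition needs no registration — and uniformly scaling the follow-up
scan by s gives contraction (1−s) × mean pre-distance exactly.
Significance uses a two-sample Mann–Whitney test between the two distance
samples (mirroring the unpaired convention used in practice); a paired
Wilcoxon on per-pair differences is emitted as a sensitivity variant.
Counts outside 3–10 landmarks warn but proceed.

## Cluster-aware statistics

* **Clustered signed-rank.**  Zeros dropped, |differences| ranked over all
  observations with average ranks, sᵢ = sign × rank; T = Σsᵢ;
  Var(T) = Σ_clusters (Σ_{i∈c} sᵢ)²; Z = T/√Var with a two-sided normal
  p-value.  For singleton clusters this is exactly the classical normal
  approximation (no continuity correction) — asserted numerically against
  scipy — and it is calibrated against the exact cluster-level sign-flip
  permutation null in the tests (the normal approximation is coarse below
  ~8 clusters; the permutation p itself has granularity 2/2^k at k
  clusters).  The location-shift CI inverts the test over a 201-point grid
  of shifts.  The front-vs-back asymmetry comparison is this same test
  applied to per-ablation front-minus-back differences.
* **Clustered correlation.**  Point estimate: Pearson r over all
  observations (Spearman variant exposed).  Inference: patient-level
  bootstrap (B = 2,000, seeded) — whole clusters resampled with
  replacement, which is vectorised via per-cluster sufficient statistics;
  p = 2·min(P(r* ≤ 0), P(r* ≥ 0)) by CI inversion.  Within-patient
  mean-centering was rejected because most patients contribute a single
  ablation.
* **Mixed-effects discrepancy model.**  ln(observed/vendor) ~ contraction
  (mm) + follow-up (days) + log tumor volume + log energy, random patient
  intercept, fitted by REML (statsmodels MixedLM; the module owns the model
  construction, transforms and reporting).  Coefficients are exponentiated
  with 95% CIs; the intercept row is the multiplicative residual
  discrepancy.  Note the intercept extrapolates to covariates = 0, so its
  CI is orders of magnitude wide by construction; the precisely estimable
  quantity is the fitted discrepancy at the covariate means, and the tests
  check the intercept by CI coverage.  A singular fit falls back to OLS
  with cluster-robust errors, with a warning.
* **Distribution summaries.**  Median, IQR, mean absolute deviation (about
  the mean), Fisher–Pearson skewness g₁, Pearson kurtosis (normal = 3),
  Kolmogorov–Smirnov-vs-fitted-normal and Shapiro–Wilk p-values (NaN below
  n = 8).  The kurtosis convention is recorded in the report metadata
  because more than one is in circulation.
* **Multiplicity.**  Holm (valid under arbitrary dependence) across the
  seven observed-vs-vendor comparisons; the front-vs-back test is reported
  alongside unadjusted.

## Synthetic cohort generator

The generator is first-class, tested code; its defaults are the cohort
conditions being emulated, and every generated parameter lands in a truth
table that recovery tests read.

* 72 patients; 70/25/5% have 1/2/3 ablations (≈97 ablations expected).
* Settings concentrated on 65 W × {5, 6, 4, 2} min with weights 18:17:14:11
  (the observed frequencies of the four most common settings).
* Volume: the vendor volume × a lognormal multiplier whose log is
  β₀ + β·covariates + patient intercept (σ = 0.2) + residual, total
  σ = 0.5 — right-skewed, heavy-tailed, with injectable fixed effects for
  model-recovery studies.  β defaults are 0.
* Shape: an egg-like body of revolution r(u) ∝ √(1−u²)(1−εu) (u = +1 at
  the distal pole).  A linear transverse taper cannot move the measured
  front/back max-width ratio far from 1 — both half-maxima sit at the
  mid-slice — so ε is solved numerically (Brent) from the requested ratio
  (default 0.9): the bulge peak sits behind the mid-slice and the measured
  ratio matches the knob.  Axes are scaled so the egg's closed-form volume
  equals the drawn target.  A smooth random radial field of spherical-
  harmonic degrees 2–4 (sums of Legendre polynomials over random axes,
  unit-rms normalised, amplitude 0.08) adds lobulation while keeping
  shapes connected and watertight, like segmented lesions; voxel noise
  would not.
* Tip offset: lognormal, median 6 mm, σ_log 0.45 (IQR ≈ 4.4–8.1 mm).
* Placement: uniformly random proper rotation and a jittered tip, written
  on a (0.8, 0.8, 1.25) mm world grid.
* Contraction: per-ablation target = 1.0 + 0.05 × follow-up days + N(0,
  1.5²) mm (median ≈ 2.5 mm at the 30-day median follow-up; occasional
  negative values = expansion).  Landmarks: pre points 5–25 mm outside the
  zone surface in random directions; post points displaced toward the
  centroid with exp(−surface distance/20 mm) attenuation.  The literal
  displacement magnitude cannot equal the target statistic (geometry
  attenuates the realised mean pairwise change by a factor ~0.3–0.5), so
  the per-ablation scale is calibrated by Newton iteration until the
  noise-free realised statistic equals the target; isotropic N(0, 0.3²) mm
  noise is then added.  This is what makes the contraction knob a
  recoverable truth.
* Follow-up: N(30, 8²) days clipped at 7; tumor volume lognormal matching
  mean ≈ 420, sd ≈ 390 mm³; categorical covariates at the observed cohort
  frequencies.

What the generator does **not** emulate: CT intensities, segmentation
noise and inter-reader variability, heat-sink deformation by real
vasculature, pleural/fissure boundary effects, and any coupling between
anatomy and shape.  Passing recovery tests therefore demonstrate that the
pipeline measures what the generator encodes at realistic scales and
noise, not that it is robust to all features of clinical data.  Under the
package's elongation convention the vendor 65 W ellipsoids are already
highly elongated (e.g. 35/18.5 ≈ 1.9), so synthetic zones do not reproduce
the observed-more-elongated-than-vendor ordering reported under other
conventions; no test depends on that ordering.

## Problem sizes and determinism

Simulation-based checks run at the scales the cohort motivates: the
recovery suite uses one ~100-ablation cohort (75 patients) for asymmetry
and contraction, 100 record-level cohorts of ~135 ablations for mixed-model
intercept coverage, 2,000 sign-flip replicates for test calibration, and
500 null cohorts for the correlation bootstrap.  The acceptance script
analyses a full 72-patient cohort end to end.  Every stochastic component
takes an explicit seed (numpy Generator); cohort analysis is deterministic
given its config seed, and two runs produce byte-identical CSVs.

## Known limitations

* The 64-mm ACCS cube truncates the proximal tail of the longest zones
  (flagged per ablation).
* The ECT embedding is not invariant to the spin convention about the
  applicator axis; two identical shapes at different spins can embed
  differently.
* The clustered signed-rank normal approximation is coarse below ~8
  clusters; for very small cohorts use the permutation approach directly.
* The bootstrap correlation p-value has resolution 1/B.
* Vendor behaviour outside the four published rows rests entirely on a
  user-supplied table.
* Masks and markups must share a world convention; none is enforced.
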