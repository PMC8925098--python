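# Methods

## Scope and data model

The package analyses single-channel 3D fluorescence stacks, axis order
(z, y, x), voxel sizes in µm (anisotropy supported everywhere volumes,
areas and lengths are computed). All intensities are normalized to [0, 1]
at load by dividing by the dtype maximum, so thresholds are unitless and
comparable across acquisitions of the same bit depth. Cohort metadata is a
CSV with one row per case (diagnosis, sex, age, post-mortem delay,
staging); the bundled 30-case table marks one DLB case as excluded from
analysis — it served antibody validation, not imaging — giving analysis
groups of 11 CTL, 10 AD and 8 DLB (29 cases).

## Segmentation

Slices are processed independently, then assembled in 3D:

1. **Noise filtering** — bilateral edge-preserving smoothing. The single
   strength parameter `sigma_noise` (default 25 px) maps to a bilateral
   spatial sigma of `sigma_noise/10`, with the range sigma set to 10 % of
   the slice's dynamic range. A bilateral filter preserves the thin
   processes that a plain Gaussian of comparable strength would erase.
2. **Background subtraction** — a Gaussian blur of the denoised slice
   (`sigma_bg`, 10–50 px, default 30) is subtracted; negatives clamp to 0.
   This removes slowly varying illumination and autofluorescence.
3. **Intensity adjustment** — a saturating linear stretch mapping the
   lower/upper `saturation_fraction` quantiles (default 1 %) to 0/1.
   Within `segment_stack` the quantiles are computed over the *whole
   stack*, not per slice: a per-slice stretch maps cell-free slices' noise
   to full range and floods the global threshold, whereas one global
   mapping preserves the meaning of a single threshold *t* across depths.
   `preprocess_slice` used standalone defaults to per-slice quantiles and
   accepts explicit limits.
4. **Richardson–Lucy deconvolution** — the multiplicative update
   `est ← est · K(img / K(est))` with a normalized Gaussian PSF
   (`psf_sigma`, default 2 px; symmetric, so the adjoint equals the
   forward blur), run `lr_iterations` times (default 10). The convolution
   is evaluated with reflective boundaries, making constant images exact
   fixed points and avoiding border attenuation.
5. **Global thresholding** — strictly greater than *t* (default 0.25).

The binary volume is labeled with 26-connectivity so thin diagonal
processes stay connected. The pipeline is deterministic; `sigma_bg` and
*t* are the two parameters intended to be tuned per stack to its noise
level, as different microscopes, tissue conservation and antibody
penetration shift both.

## Artifact removal

Three gates, applied to measured cells:

* **Volume window** [48 000, 216 000] µm³, inclusive at both bounds.
  Objects below are debris or fragments; above are merged accumulations of
  several cells (e.g. plaque-associated clusters), which are discarded
  rather than split — instance-splitting of touching cells is out of scope.
* **Border contact**: cells are removed when border_area / face_area is
  strictly greater than 0.075. Two surface estimators coexist by design:
  `face_area` counts exposed voxel faces (exactly defined at stack
  boundaries, used only for this gate), while `mesh_area` is a marching-
  cubes isosurface area (used for shape features; face counting
  overestimates smooth areas by a large constant, ~1.5× for a sphere).
* **Boosted-tree classifier** (optional; needs manual labels): AdaBoost
  over depth-2 trees, k-fold cross-validated (default k = 5), seeded and
  fully reproducible. Serialization exports the tree arrays and stage
  weights to JSON; a loaded classifier re-predicts from those arrays.

The volume and border gates commute; order is immaterial.

## Skeleton graphs and features

Masks are thinned with 3D medial-axis thinning. Skeleton voxels with ≠2
neighbours (26-connectivity) become node voxels; adjacent junction voxels
merge into one node at their centroid; chains of degree-2 voxels become
edges whose geodesic length sums anisotropic step lengths (a diagonal x–y
step contributes √(dx²+dy²) µm). Terminal spurs shorter than
`spur_min_length` (default 2 µm) are pruned — they are thinning artifacts
at junctions — and pass-through nodes left by pruning are re-merged. A
blob with no branches yields the degenerate graph N=1, E=0. Pure cycles
(possible after noisy segmentation) anchor one node and appear as
self-loops; self-loops are excluded from tortuosity.

The 16 features and their conventions:

| feature | definition | degenerate convention |
|---|---|---|
| volume | voxel count × voxel volume (µm³) | — |
| mesh_area | isosurface area (µm²) | — |
| compactness | (36π V²)^⅓ / mesh_area | 1 for a ball; ↓ with ramification |
| polarity | λ₁/Σλ of coordinate covariance | ⅓ (isotropic) for <2 voxels |
| bound1, bound2 | two largest PCA-oriented extents (µm) | 0 for a point |
| node_density | N/V (µm⁻³) | — |
| ending_node_density | N_end/V (µm⁻³) | — |
| avg_node_degree | 2E/N | 0 for N=0 |
| link_density | 2E/(N(N−1)) | 0 for N<2 |
| s_metric | Σ_edges deg(u)·deg(v) | 0 for E=0 |
| volume_per_edge | V/max(E, 1) | — |
| mean/max edge length | over branch geodesics (µm) | 0 for E=0 |
| total_skeleton_length | Σ branch geodesics (µm) | 0 for E=0 |
| mean_tortuosity | mean geodesic/Euclidean per branch | 1 for E=0 |

Extents are PCA-oriented (not axis-aligned) so they are rotation-stable.
Node densities are normalized by cell volume; a per-node alternative can
be derived trivially from the stored counts. The registry (`FEATURE_NAMES`)
fixes the canonical column order used by normalization, clustering and
feature selection.

## Clustering

Per-feature range normalization to [0, 1] over the complete analyzed set
(constant features map to 0), Ward minimum-variance agglomeration under
Euclidean distance, tree cut at k = 7 — the number of morphological
clusters the analysis is designed around; no automatic k selection is
attempted. Labels are renumbered by descending cluster size so cluster 1
is always the most abundant. The UMAP embedding is seeded, deterministic,
and used for plots only; it never enters statistics. Abundance tables give
the percent composition of clusters per case × subfield (rows sum to 100).

## Pathology loads

The volumetric score of a marker stack replaces an interactive commercial
surface-reconstruction workflow with an equivalent open pipeline: Gaussian
smoothing (`smoothing_sigma`, the "surface detail" scale), an absolute
threshold (strict), 26-connected components, an optional minimum object
volume, and percent of stack volume covered. The score is monotone
non-increasing in both the threshold and the minimum object volume, and
with smoothing off equals the exact thresholded voxel fraction. One
parameter set per marker is applied across all cases and subfields. For
the synthetic blob stacks (background 0.05, stain 0.9) the near-unbiased
setting is light smoothing (σ = 0.5) with the threshold just below the
half-contrast midpoint (0.45), which recovers planted fractions to within
a few hundredths of a percentage point; a threshold above the midpoint
erodes convex blobs in proportion to curvature × σ².

## Statistics

* **Mann–Whitney U**, two-sided: exact enumeration when n₁+n₂ ≤ 12 with no
  ties, tie-corrected normal approximation with continuity correction
  otherwise. The exact branch is cross-checked in the tests against a
  brute-force enumeration oracle over all rank assignments.
* **Spearman correlation** with average-rank ties, p from the
  t-approximation; R²_Spear = ρ² is reported alongside. Constant inputs
  raise rather than return NaN.
* **Feature reduction**: greedy scan in canonical order; drop a feature
  when |Pearson r| with any already-retained feature exceeds 0.80. The
  rule is order-dependent by construction (the earlier feature of a
  correlated pair is kept); constant features are retained (their
  correlation is undefined).
* **Cohort descriptives**: arithmetic group means of age and PMD and
  percent female, rounded to one decimal with halves away from zero,
  computed with exact (fsum) summation so results do not depend on the
  array library's summation order. The bundled table's printed-style
  labels call the age statistic a median; the values reported here are
  means, which is what the group numbers correspond to.
* Significance at 5 % throughout; no multiple-testing correction, in line
  with the explorative character of the correlation screens. The
  correlation matrix runs one Spearman test per (variable, marker,
  subfield) on case-matched samples and marks cells with n < 3 undefined.

Group tests on cohort data default to per-case aggregates (cells averaged
within case × subfield before testing), avoiding pseudoreplication from
thousands of cells per case; pooled-cell testing is possible by passing
cell-level rows directly.

## Synthetic data: what it emulates and what it does not

`sample_tree` grows random branching trees (primary branches from a soma,
segment lengths ~N(14, 2) µm bounded below by 0.8× the mean, bifurcation
probability 0.4 to depth 3, growth compressed 2× in z to mimic laterally
extended cells in thick sections). Segments that would pass within one
tube diameter + 6 µm of a non-adjacent branch are re-aimed or dropped, so
the planted simplified graph (degree-2 chains contracted) is exactly the
topology of the rasterized cell — the property the recovery tests rely on.
`render_scene` rasterizes tubes (radius 3 µm) at 0.8 intensity into a
64×192×192 stack at 1 µm isotropic voxels, applies Gaussian PSF blur
(σ = 1 voxel), an illumination ramp (amplitude 0.1) and Gaussian noise
(SD 0.05), placing cells by rejection sampling with ≥8 µm clearance
between tube surfaces (largest trees first). `make_pathology_stack` adds
spherical blobs until a target volume fraction is hit within 0.2
percentage points and records the exact fraction. `simulate_cohort` draws
case-level random effects around planted condition shifts, cell-level
noise around those, and marker loads coupled linearly to the case-level
feature deviations.

Scenes rendered under these defaults are analysed with segmentation
parameters matched to the imaging model — saturation 0.002 (the foreground
occupies <1 % of a scene, far sparser than real tissue, so the stretch
quantile must sit above the foreground fraction), PSF σ = 1 matching the
rendered blur, threshold 0.3 — and branch graphs with spur pruning at
5 µm, half the minimum planted branch length. This mirrors the per-stack
tuning the method prescribes for real data.

What passing these tests shows: the geometry, graph extraction, gating,
clustering and statistics are correct, and the segmentation recovers
known topologies through realistic blur, noise and uneven illumination.
What they do not show: performance on real tissue — true microglia have
sub-voxel processes, intensity falls off with depth, cells touch and merge
near plaques, and artifact morphologies are richer than anything the
generator plants. The deliberate exclusions (touching cells, photometric
depth decay, autofluorescence spectra) are listed as generator non-goals.

## Numerical choices and edge cases

* Threshold comparisons are strict (>) in segmentation and load scoring;
  the volume gate is inclusive at both bounds; the border gate is strict —
  boundary cases are covered by tests.
* Richardson–Lucy clips intermediates at 1e−12 to avoid division by zero;
  constant slices are exact fixed points.
* Degenerate stretch ranges (constant slices) map to all-zero output.
* Ward clustering is deterministic; ties in cluster-size renumbering break
  by original label for stability.
* Problem sizes in tests and the acceptance script (5-cell 64×192×192
  scenes, 700-cell clustering, 1000-replicate calibration loops) are the
  package's desk-scale defaults, chosen so the whole suite runs in a few
  minutes on one CPU core.

## Known limitations

* Deconvolution is 2D in-plane; the axial PSF is not inverted (slice-wise
  design), so masks carry ~1 voxel of z-softening and Dice against planted
  tubes plateaus near 0.9 even when topology is exact.
* The 13 named features are fixed; the three registry slots filled here
  (mesh area, total skeleton length, mean tortuosity) are package choices
  consistent with the morphological/graph split, and the registry is
  pluggable if a different completion is preferred.
* No automatic threshold selection: per-stack tuning is manual via
  configuration, by design.
* The artifact classifier requires manual labels and is off by default;
  the two geometric gates alone form the standard path.
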