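# micmac

Automated 3D morphometry of microglia — the brain's resident immune cells —
from single-channel confocal stacks, together with volumetric quantification
of misfolded-protein pathology burdens (hyperphosphorylated tau, amyloid-β,
phosphorylated α-synuclein) and the nonparametric statistics that relate the
two.

Microglia morphology tracks their functional state: surveillant cells are
highly ramified, activated cells retract branches and become amoeboid. This
package measures that remodelling cell by cell in post-mortem tissue
volumes, for neuropathology groups studying how local pathology loads shape
microglial phenotypes across hippocampal subfields (CA1, CA3, DG/CA4) and
diagnostic groups (control, Alzheimer's disease, dementia with Lewy bodies).

## What it computes

**Segmentation.** Each z-slice of an Iba1 stack passes through
edge-preserving denoising, Gaussian background subtraction (σ ∈ [10, 50]),
a saturating contrast stretch, Richardson–Lucy deconvolution with a
Gaussian PSF, and a global intensity threshold *t*; the binary volume is
then 26-connected-component labeled into candidate cells.

**Artifact removal.** Three gates: keep cells with volume in
[48 000, 216 000] µm³ (inclusive); remove cells whose surface on the stack
border exceeds 7.5 % of their exposed surface (strict); optionally an
AdaBoost boosted-tree classifier trained on manually labelled artifacts,
validated by k-fold cross-validation.

**Morphology features.** Each cell mask is thinned to a medial skeleton and
converted to a branch graph: nodes are junctions and endpoints, edges are
branches with geodesic lengths in µm (anisotropic voxel sizes respected).
Sixteen features per cell: volume *V*, smooth surface area *A*, compactness
(sphericity) (36π V²)^⅓ / A, polarity λ₁/(λ₁+λ₂+λ₃) of the coordinate
covariance, the two largest PCA-oriented extents, node density N/V, ending
node density N_end/V, average node degree 2E/N, link density 2E/(N(N−1)),
s-metric Σ_edges deg(u)·deg(v), volume per edge, mean/max edge length,
total skeleton length, and mean tortuosity (geodesic/Euclidean per branch).

**Clustering.** Features range-normalized to [0, 1] over the complete cell
set, Ward minimum-variance agglomeration cut at k = 7 morphological
clusters, abundances tabulated per case × subfield, and a seeded UMAP
embedding for visualization only.

**Pathology loads.** Per marker stack: smooth, absolute threshold,
3D components, and the score = percent of stack volume covered.

**Statistics.** Two-sided Mann–Whitney U tests (exact for small tie-free
samples, tie-corrected normal approximation otherwise), Spearman rank
correlations with R²_Spear reported, greedy Pearson feature reduction
(|r| > 0.80), and cohort descriptives. Significance at 5 %, uncorrected.

A synthetic-data module generates ground-truthed fixtures for every stage:
branched tube cells in noisy unevenly lit stacks, pathology stacks with
known volume fractions, and hierarchical cohorts with planted effects.

## Worked example

`examples/01_segment_synthetic_scene.py` renders five branched cells into a
noisy 64×192×192 stack and segments them:

```
rendered stack (64, 192, 192) voxels, 5 planted cells
segmentation found 212 candidate objects
  cell 1: planted 2583 voxels, Dice = 0.914
  cell 2: planted 4224 voxels, Dice = 0.916
  ...
```

Dice is the overlap between the recovered and planted 3D masks (1 = exact);
the extra candidate objects are small noise specks that the volume gate
removes. `examples/02_skeleton_features.py` prints the full 16-feature
vector of one cell and shows the branch graph matching the planted tree
exactly (6 nodes, 5 edges, 4 endpoints). `examples/05_cohort_statistics.py`
reproduces the bundled cohort's descriptives:

```
CTL: n=11, mean age 83.1 y, mean PMD 22.5 h, 54.5% female
AD: n=10, mean age 87.1 y, mean PMD 23.1 h, 30.0% female
DLB: n=8, mean age 77.3 y, mean PMD 19.4 h, 37.5% female
```

and flags a planted compactness–pTau coupling as significant positive
Spearman cells in all three subfields.

A thin CLI wraps the same library calls
(`micmac segment|filter|features|cluster|load|stats|simulate`); see
`micmac --help`.

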