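# Methods

This note documents the models, numerical conventions and design
choices behind `shrubscan`, and what the synthetic test bed does and
does not demonstrate about real surveys.

## Terrain model and layering

The DTM is the per-cell minimum return height on a fixed grid (default
1 m). A fixed grid rather than an overlapping moving window keeps the
result independent of evaluation order and reproducible; at 1 m support
the two differ only at cell boundaries. Empty cells are filled from the
nearest filled cell by planar centre distance, ties resolved by
row-major scan order. NormZ = z − DTM(x, y) may be slightly negative
where returns scatter below the minimum surface; values below −0.05 m
are clamped and the return is flagged as noise (upstream noise
filtering of a real survey is outside this package's scope).

Layer bands: ground [−0.05, 0.15), low vegetation [0.15, 0.30), shrub
layer [0.30, 3.50], high vegetation (3.50, ∞), in metres of NormZ. The
interval ends 0.30 and 3.50 are assigned to the shrub layer so that no
point is left unlabelled. A known consequence of minimum-based
normalization is upward leakage: where the terrain slopes within a DTM
cell, tall grass can exceed 0.30 m NormZ and enter the shrub layer.
This is a property of the method, not of the simulator — the
shrub-absence reference class exists to teach the classifier that such
points are not shrubs.

## Structural features

All neighbourhoods are closed balls (distance ≤ r). Counts and means
include the focal point; pairwise distance and angle means exclude it.
Sentinels for degenerate neighbourhoods (variance 0, rank 100, openness
90°, distance = r_small) are the least informative plausible values, so
an isolated point biases no class. The plane fit behind the
pseudowaveform is orthogonal least squares (normal = eigenvector of the
smallest covariance eigenvalue), and the reported value is the
population variance of the signed orthogonal residuals; orthogonal
rather than vertical residuals make the feature invariant under rigid
rotation. With a degenerate (collinear) neighbourhood the eigenvector of
the smallest eigenvalue is canonicalized to a non-negative z (then y,
then x) component. The ground-point count uses a vertical cylinder, not
a sphere: a 0.1 m sphere around an elevated canopy point can never
contain ground echoes, which would contradict the attribute's meaning
as a light-penetration measure. The echo-count feature is the
neighbourhood mean of each pulse's total return count.

Variable selection computes leave-one-out importance as the decrease in
mean overall accuracy over stratified splits when one variable is
omitted (10 splits by default — enough to stabilize the ranking at a
fraction of the full validation cost), then greedily drops the
lower-importance member of every pair with Spearman |ρ| > 0.75.

## Classifier

The decision tree is grown by exhaustive binary Gini splits. Candidate
thresholds are midpoints between consecutive distinct values; equal-gain
ties resolve to the earlier feature column, then the smaller threshold,
making training deterministic for a given row set. Pruning follows the
classical complexity-parameter convention: bottom-up, a split (with its
subtree) survives only if it reduces the misclassification risk by
strictly more than cp × (root risk). The strict inequality matters at
the boundary: at cp = 1 even a perfect root split (risk improvement
exactly equal to the root risk) is pruned, giving a root-only tree.
Leaves store training class proportions; prediction returns these as
fuzzy memberships, with the hard label the argmax (ties to the class
earlier in schema order). Stratified splits put floor(n · frac) rows of
each class into training, never emptying either side for classes with
n ≥ 2; single-row classes cannot be stratified and are either an error
(library) or dropped with a warning before validation (pipeline), since
a class observed once cannot be validated. Accuracy metrics (overall
accuracy, Cohen's κ with chance agreement Σ row·col / total², per-class
precision/recall/F1) are computed directly from the confusion matrix;
per-class measures are NaN when their denominator is empty.

## Biomass and change

Pixel volume is statistic(NormZ) × cell² (default 5 cm cells, so
25 cm²); `max` is the default statistic, being the best-performing
metric of the shipped reference fits. Shrub footprints are the 2-D
convex hull of the delineation points — deterministic and order-free —
and a pixel contributes when its centre lies inside or on the hull.
The allometry is a per-shrub regression; applying it per 5 cm pixel
replicates the intercept over every occupied pixel, which inflates
absolute landscape totals (totals then scale with occupied canopy
area as well as volume). Both application modes are provided:
`per_pixel` (the default) and `per_segment`, which applies the model
once per 8-connected segment and distributes mass proportionally to
pixel volume. Per-segment totals are dimensionally cleaner for compact
shrubs but are sensitive to speckle — isolated misclassified pixels
each earn a full intercept — so the pipeline and acceptance runs report
the per-pixel form and treat the change map, where stable occupancy
cancels the intercept, as the robust quantity.

Change is epoch 2 minus epoch 1 per pixel (negative = decline), masked
to cells where both epochs have ≥ 2 returns and a mean 3-D
nearest-neighbour spacing below the cutoff, then summed into 2.5 m
cells (50 × 50 pixels; edge blocks sum what exists). The spacing rule is
evaluated per 2.5 m reporting cell. Both epochs snap to a shared origin
(joint lower-left bound rounded down to a cell multiple), so
co-registration is bit-reproducible. The 3 cm default cutoff presumes
field point densities (> 1,000 pts/m²); synthetic desk-scale scenes are
scanned at ~7 cm pulse spacing, so tests and the acceptance run use a
commensurate 12 cm cutoff.

## Synthetic scenes

The generator emulates what the features consume — geometry and echo
counts — not radiometry. Terrain is a smooth sinusoid mixture
(amplitude 0.4 m, correlation length 10 m by default, comparable to the
relief a 1 m minimum-DTM must absorb); grass is 2–25 cm tall with 40%
bare-ground hits. Vertical pulses on a jittered grid (default 7 cm
spacing, ≈ 200 pulses/m² — a deliberate scale-down of field densities
that keeps feature neighbourhoods populated) return the first surface
hit; canopy pulses gain a second, ground echo with the archetype's
penetration probability, and canopy interiors are filled with
volumetric returns at the archetype's point density. Three default
archetypes span the feature contrasts: a dense erect ellipsoid with
moderate penetration and frequent dual echoes ("broom"), a compact,
smooth, nearly opaque hemisphere ("conifer"), and a sparse, rough,
elevated crown with clear trunk space ("tree_overhang"). Per-shrub
biomass is a + b·volume + N(0, σ) truncated at zero, with defaults
(80 g, 4,700 g/m³, 50 g) on the scale of the shipped reference fits.

All randomness flows from the scene seed through counter-based streams:
the pulse grid, the grass layer (drawn per pulse, not per uncovered
pulse) and each shrub (keyed by its position in the placement list) are
independent, so removing trailing placements leaves every other
return bit-identical — the foundation of the change-detection tests.
Survey emulation produces one reference record per shrub (gathering
radius = canopy radius) plus shrub-absence records over open ground,
and harvest records with 25-point delineation rings whose hull closely
matches the true circular footprint.

What passing tests show — and don't. The synthetic archetypes are
deliberately well separated; the ~92% overall accuracy they yield
demonstrates that the feature/classifier machinery extracts the
intended contrasts, not that any particular real taxa pair is
separable. Real clouds add registration error, scan-angle effects,
seasonal change and taxa with overlapping structure; accuracy there is
a property of the data. Likewise the simulator's independently trained
per-epoch classifiers shift their confidence between epochs (as
leaf-on/leaf-off surveys do), which adds change noise on the order of a
single shrub; the acceptance scenario therefore removes three shrubs so
the true signal dominates.

## Problem sizes and determinism

Default test and acceptance scenes are 20 × 20 m with 24 shrubs
(~100k returns, ~30k shrub-layer points); validation uses 20 stratified
iterations where the full protocol would use 100. Every stochastic
stage takes an explicit seed, and the pipeline derives per-stage seeds
from a single run seed by hashing, so one integer reproduces a run
bit-identically.

## Known limitations

- LAS support covers point formats 0–3 with the package's own
  extra-bytes layout; VLR metadata, waveforms and CRS transformations
  are out of scope.
- The DTM is a minimum filter with nearest-cell fill; no TIN/kriging
  interpolation or slope-adaptive ground classification.
- Segmentation of individuals is limited to 8-connected raster
  components; touching shrubs merge into one segment.
- Only two survey epochs are compared; no multi-epoch time series.
- Class imbalance is left as-is (no weighting) to match the reference
  protocol; a weights hook exists in the training API for reuse.
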