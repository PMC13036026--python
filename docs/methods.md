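# Methods

`fosmap` reimplements, at desk scale, a whole-brain c-Fos mapping workflow:
fluorescent puncta are detected in 3-D cleared-tissue volumes, deduplicated,
classified as cells or artifacts, mapped through a deformation field onto a
hierarchical brain atlas, aggregated into per-animal regional densities, and
analyzed with a region-selection + mixed-model effect-size stack that
classifies brain structures as treatment-responsive, with time and sex
interactions. This note records the models, the parameters that matter, and
the design choices made where the design was genuinely open.

## Detection

Two complementary detectors run over each volume, both deliberately biased
towards over-detection so no cell is missed; precision is restored later by
the classifier.

**Conventional (LoG).** The volume is filtered with a negated
Laplacian-of-Gaussian at the puncta scale (default sigma (3.0, 1.5, 1.5) µm
in z, y, x — a typical PSF-elongated confocal punctum; the axial sigma is
below the 5.33 µm z-pitch, so puncta are nearly single-plane in z). Local
maxima above `threshold_sd` robust standard deviations (MAD x 1.4826) of the
response are kept. The default `threshold_sd = 2.0` is deliberately low:
under Gaussian noise it admits many false maxima, which is the intended
over-detection bias.

**Matched filter (NCC).** Normalized cross-correlation with a zero-mean,
unit-norm Gaussian template, thresholded on the correlation (default 0.35).
Because the correlation is locally normalized it is intensity-scale-free:
it recovers dim puncta in quiet regions that a globally-thresholded detector
loses when high-variance autofluorescent tissue elsewhere inflates the
global threshold. The 0.35 default sits between the noise-only correlation
ceiling (~0.12 for templates of this size) and the response of a punctum at
local SNR ~3 (~0.35-0.40; the local variance in the denominator includes the
signal itself, which is why an "SNR 3" spot does not correlate at 0.5).

Sub-voxel centroids are intensity-weighted means over a 1-sigma
neighbourhood — essential in z, where one voxel (5.33 µm) exceeds the 5 µm
matching radius. All coordinates are world micrometres; voxel units are
never compared across axes. Candidates within 3·sigma of a volume face are
kept but flagged `near_border`; the classifier sees a border-distance
feature and removes edge artifacts itself.

**Foreground mask.** Otsu on a Gaussian-smoothed copy (5 µm), keeping the
largest connected component. Two robustness measures: intensities are
clipped at the 90th percentile before Otsu (sparse bright structures —
puncta, vessels — must not set the tissue threshold), and the mask is
dilated back by one smoothing width (smoothing erodes the tissue boundary;
border cells must not be masked out). A contrast-free volume returns an
all-true mask with a warning rather than silently dropping everything.

**Consolidation.** Both detectors report the same cell, so the union is
clustered with DBSCAN in world-µm space (eps = 5 µm, matching the 5 µm
intersection radius of the validation protocol; min_samples = 1 so
singletons survive). Each cluster is replaced by the unweighted centroid of
its members, carrying the maximum member intensity. The operation is
idempotent at fixed eps. Note one consequence: two true cells closer than
eps can merge, so consolidated recall can sit slightly below raw-union
recall in very dense fields.

**Matching.** Validation uses one-to-one optimal assignment
(`linear_sum_assignment` on the distance matrix, infeasible pairs priced
above any feasible matching) among pairs within the matching radius
(default 5 µm): maximum cardinality first, then minimum total distance.
Greedy matching would make F1 order-dependent. Precision = matched/n_pred,
recall = matched/n_truth.

## Classification

Each consolidated spot is reduced to eight patch features (10 µm radius):
core peak intensity, patch mean and SD, peak-to-annulus contrast ratio,
second-moment anisotropy (sqrt of extreme eigenvalue ratio in µm²,
regularized by the voxel second moment so single-voxel spikes stay finite),
border distance, planarity (largest fraction of above-background patch
energy in a single plane), and elongation (the largest over axes of the
background-normalized intensity sustained at BOTH patch ends along that
axis). The features target the three artifact classes: edge planes
(planarity high), vessel tubes (anisotropy and elongation high), noise
spikes (anomalous contrast at tiny spatial extent). Elongation exists
because second moments alone miss a vessel running along the low-resolution
z axis: the annulus background estimate contains the structure itself, so
each tube cross-section looks punctum-like; probing the patch ends is
immune to that self-subtraction. A z-oriented tube also evades DBSCAN
consolidation (its detections sit one 5.33 µm z-step apart, beyond the
5 µm eps), so the classifier is the only stage that can remove it.

A 200-tree random forest (seeded, single-thread) predicts P(cell);
`is_cell = score >= 0.5`. The threshold is fixed rather than tuned per
brain — per-brain tuning would leak the validation patch. Fine-tuning
refits the forest on the original manifest plus new locally-annotated
examples weighted x5: strong enough that 50-200 annotations move the
boundary, weak enough that the base training set is not forgotten. The
original model object is never mutated.

Brains are accepted when detection + classification reaches F1 strictly
above 0.80 against a manually annotated ROI patch at 5 µm matching; a
rejected brain's manifest records that fine-tuning is required.

## Atlas model and mapping

The ontology is a flat-list structure graph (id, acronym, parent, volume,
gray-matter flag) validated into a tree; depths are recomputed, never
trusted from the file. Parents may exceed the sum of their children
(unannotated interior volume) but never the reverse beyond 1e-6 mm³.

Deformation fields are gridded displacement vectors (sample -> atlas, µm),
interpolated trilinearly at spot positions; points beyond the grid are
clamped to the border and flagged rather than dropped (registration edges
are imperfect; silent dropping would bias border regions). The inverse
direction is deliberately unsupported. Region assignment is nearest-voxel
label lookup — labels are categorical, so no partial-volume interpolation.
Label 0 and out-of-volume spots stay unassigned: they count in whole-brain
totals but are excluded from all region statistics. The label volume is
hemisphere-symmetric (left and right share ids), so hemisphere counts
combine automatically.

Aggregation produces direct counts (exact label), cumulative counts
(+ all descendants) and densities (cumulative / structure volume,
cells/mm³). The wide-format density matrix has one row per animal and one
column per region acronym in depth-first ontology order; a region with no
detected spots is density 0, never missing. Cohort heatmaps partition the
anterior-posterior axis into 1 mm slabs, histogram spot positions at atlas
voxel resolution, divide by the group's animal count, and smooth with a
100 µm Gaussian (a visualization choice; pre-smoothing slab mass is exactly
spots/n_animals).

## Statistics

**Region pre-selection.** A random forest (300 trees) classifies treatment
from the density matrix; stratified K-fold CV F1 is reported with folds
capped at the smaller class size (a 27-animal factorial cohort cannot
always fill 10 stratified folds), then a final forest is fit on all
animals. Regions with nonzero impurity importance are selected, and any
selected structure with a selected strict descendant is pruned
("descendant", not "direct child" — otherwise a grandparent with only
grandchildren selected would leak through, defeating the multicollinearity
rationale). The survivors form an antichain in the ontology.

**Per-region model.** Each surviving region gets
`density ~ treatment * time * sex` (full factorial including the three-way
term), reference cell (saline, 1h, male), with a random intercept per
mouse. With repeated measures per mouse the model is fit by REML
(statsmodels MixedLM). The wide density matrix has exactly one observation
per mouse per region, so the intercept/residual split is unidentifiable;
only the sum sigma²_e + sigma²_u is meaningful, and in that case the fit
runs through OLS, which estimates identical fixed effects and the same
identifiable total variance (MSE on n - p df), reporting the intercept
share as 0. Downstream quantities use only the sum, and a dedicated test
checks d is invariant to the split. An empty design cell raises an error
naming the cell.

**Effect sizes.** For a contrast vector c: d = c'beta / sqrt(sigma²_e +
sigma²_u); the 95% CI scales the Wald CI of c'beta by the same total SD
(the SD is treated as known — no small-sample correction), and p-values are
two-sided normal (Wald) tests. Group contrasts compose interaction terms,
e.g. the morphine effect in 4h females is beta_treat + beta_treat:time +
beta_treat:sex + beta_treat:time:sex. Zero total variance with a zero
contrast reports d = 0 (the degenerate all-constant cohort); with a nonzero
contrast it raises, since d is then undefined.

**FDR and classification.** Benjamini-Hochberg step-up q-values are
computed within each contrast family across regions (per-family control is
the conservative reading of per-figure starring; pooling families would mix
eight hypothesis types). A region is *responsive* when any of the four
treatment group contrasts has |d| > 0.8 AND a CI excluding 0; time/sex
difference sets apply the same rule to the interaction contrasts. Stars
mark q < 0.05/0.01/0.001. The q < 0.05 rule marks significance; the
responsive rule deliberately does not require it (corrections across
hundreds of regions are too stringent for subtle effects).

The model/results pair `RegionResponseModel` / `RegionResponseResults`
bundles this stack behind a `fit()` returning estimates, uncertainties,
the classification report and a `summary()` table.

## Synthetic data

The generators define the conditions every test runs under.

*Toy atlas*: a margin-bounded tissue block split along the
anterior-posterior axis into leaf slabs (seeded random boundaries, >= 2
voxels each) grouped into lobes under one root; mirror-symmetric in x by
construction; all volumes exact integer voxel counts x voxel volume.

*Volume phantoms*: puncta counts per region are Poisson(rate x region
volume); centers are uniform over region voxels with sub-voxel jitter;
each punctum is an anisotropic Gaussian with amplitude jitter x U(0.6, 1.5)
and width jitter x U(0.8, 1.25) ("different sizes and intensities");
default amplitude 100 over background 20 with noise SD 10, so the dimmest
puncta sit at SNR ~6. The default grid is 100 x 512 x 512 at (5.33, 0.361,
0.361) µm — the acquisition pitch of the majority of the study's brains.
Artifact classes: 1-voxel bright planes at volume faces, 2 µm-radius bright
tubes through the tissue along a random axis, and single-voxel spikes.
Truth tables list every punctum's world-µm center and region; artifacts are
excluded. What the phantom does **not** model: depth-dependent attenuation
and scattering, stitching seams, striped illumination — so passing gates
here show algorithmic correctness, not robustness to those acquisition
pathologies.

*Cohorts*: the factorial design uses the study's group sizes (M-1h-m 5,
M-1h-f 3, M-4h-m 4, M-4h-f 3, S-1h-m 3, S-1h-f 2, S-4h-m 3, S-4h-f 4;
N = 27, 15 males / 12 females). Per animal a mouse intercept
u ~ N(0, sigma_mouse²) is shared across regions; per region, density =
baseline + total_SD x (d_treat·I[morphine] + d_treat:time·I[morphine&4h] +
d_treat:sex·I[morphine&female]) + u + N(0, sigma_resid²). Scaling the
injected effects by the total SD makes the injected quantity exactly the
Cohen's d the analysis should recover, which keeps parameter-recovery tests
well-posed. Default noise: sigma_mouse = 40, sigma_resid = 60 cells/mm³
(20%/30% of a 200 cells/mm³ baseline — fixture choices, as no per-group
variance components are available to copy); recovery suites use baseline
500 cells/mm³ >= 5 x total SD so zero-clipping (logged with a warning) is
negligible.

*Deformations*: identity, constant translation, or a seeded low-frequency
random field rescaled so the maximum displacement norm equals the requested
magnitude.

## Reference benchmarks and problem sizes

`fosmap.reference` holds the seeded end-to-end gates. The detection gate
renders the reference phantom (~220 expected puncta, 2 edge planes, 3
vessels, 10 spikes on the full 100 x 512 x 512 grid), trains the classifier
on two disjoint phantoms (seeds seed+1, seed+2) by labeling their pooled
detections against truth — multi-brain training covers independent artifact
orientations —
and reports F1 of detect -> consolidate -> classify at 5 µm matching.
Parameter recovery runs 120 mixed cohorts (d in {0, 1, 2} over 20 regions)
plus 80 global-null cohorts at the N = 27 design: mean d-hat per true
value, CI coverage, per-family null q < 0.05 rates, and responsive-flag
sensitivity at d = 2. These sizes keep the full suite to a few minutes
while leaving Monte-Carlo standard errors well below the tolerances they
are checked against.

## Pipeline

`run_pipeline` executes atlas -> classifier -> per-brain (simulate, detect,
classify, map, aggregate) -> densities -> stats from one YAML config. Each
stage writes a JSON manifest with the SHA-256 of its inputs and outputs and
its parameters; a stage is skipped when its manifest still matches, so
deleting one downstream artifact recomputes only that stage. Stage
resumability via checksum manifests rather than a workflow engine keeps the
package dependency-light. A run is a pure function of (config, seed, input
files); repeated runs are byte-identical. Counts are logged per stage and
conservation is asserted (cells <= consolidated detections; assigned +
unassigned = cells).

## Known limitations

- The per-region model cannot separate mouse-intercept from residual
  variance on one-observation-per-mouse data; only their sum is reported
  meaningfully. A joint model over regions as repeated measures would
  identify the split but is not implemented.
- d CIs treat the estimated total SD as known; with 19 residual df the
  realized coverage of a nominal 95% interval is ~92-94%.
- The matched filter shares its template scale with the LoG detector;
  puncta far from that scale degrade both detectors together.
- The phantom's artifact classes are stylized; classifier performance on
  real autofluorescence is bounded only by the fine-tuning contract, not by
  these tests.
- Whole-brain density denominators use total annotated volume; densities in
  structures with substantial unannotated interior are underestimates.
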