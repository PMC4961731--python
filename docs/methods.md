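# Methods

This note documents the models, algorithms, parameters and numerical
choices behind `spinecarve`, and what its synthetic test bed does and
does not demonstrate.

## Problem setting

The input is a 3D CT volume in Hounsfield Units (HU) together with an
axis-aligned bounding box assumed to enclose one vertebra (plus
possibly fragments of its neighbors). The output is a binary voxel
mask of the vertebra. No shape prior is used anywhere: the method is
meant to survive the shape and density alterations that make
atlas- or template-based segmentation fragile (arthrosis, hernia,
compression, osteolytic/osteoblastic lesions, cementoplasty, nearby
air).

Segmentation proceeds in two stages: a coarse, fully deterministic
**carving** stage that removes non-vertebral supervoxel clusters from
the box, and a fine Bayesian stage that classifies every voxel of a
region of interest (ROI) with a two-class **hidden Markov chain**
(HMC) along a shape-adapted space-filling spiral.

Conventions: array axes are (x, y, z) with z axial; voxel indices are
0-based; bounding boxes are half-open; all distances are physical
(index x spacing, in mm); HU values are never rescaled at I/O time.

## Coarse stage: supervoxel carving

Each iteration j isolates the current outer **layer** of the
remaining volume V with physical-ball morphology,

    V_1 = V_0 − (V_0 ⊖ R(I_1)),
    V_j = (V ⊕ R(O_j)) − (V ⊖ R(I_j)),   j > 1,

where R(a) is the Euclidean ball of radius a mm. The outer band O_j
re-examines voxels near the previous boundary so that a borderline
decision can be revised at a finer scale. Erosion and dilation are
computed through exact Euclidean distance transforms (a voxel
survives erosion iff no background voxel lies within the radius),
which is identical to the classical structuring-element operations on
a lattice but linear in the volume size.

The layer is partitioned into **supervoxels** by a 3D, masked
generalization of SLIC: voxel i carries features
(x_i, y_i, z_i, l_i); a cluster centroid is the feature mean of its
members; assignment minimizes

    D_m = sqrt( (d_c/m)^2 + (d_s/S)^2 ),

with d_s the Euclidean distance (mm), d_c the absolute luminance
difference (HU), S the expected supervoxel spacing (mm, physical so
anisotropic voxels behave correctly) and m the
luminance-versus-space weight. Seeds start on a regular physical grid
of step S; because carving layers are thin shells that a coarse grid
can miss entirely, grid nodes falling outside the mask are snapped to
the nearest in-mask voxel within S and deduplicated. Each centroid
competes only inside a cubic window of physical side 2S; voxels no
window reaches (possible for ragged masks) are assigned to the
globally nearest centroid in a final sweep so the partition invariant
always holds. Ties go to the lower cluster id; empty clusters are
dropped; no connectivity enforcement is applied by default (clusters
may be disconnected; a config toggle can split them).

Each cluster k (size |k|, mean luminance l_k) is then tested by the
**vertebral predicate**. The bone half is a statistical-region-merging
test against a reference bone luminance l0:

    accept if |l_k − l0| ≤ b(k),   b(k) = g · sqrt( ln(1/δ) / (Q·|k|) ),

with g the intensity range of the current layer, δ the acceptable
error probability, and Q the statistical complexity of the region.
The interiority half accepts any cluster that lies closer to the
remaining-volume centre v than some already-accepted 26-adjacent
neighbor, propagated to a fixed point — vertebrae are compact, so
anything enclosed by accepted bone belongs to the result even when
its luminance is not bone-like (trabecular interior, spinal canal
content inside the arch ring). v is the center of mass of the
remaining volume, recomputed every iteration.

Accepted clusters stay; rejected clusters are removed from the
remaining volume. The loop runs

    J = 2 + ceil( (h − S1 − S2) / Sj )

iterations (h = box height along z, the shortest box dimension for
vertebral volumes; floored at two iterations), or stops early when a
layer comes out empty. Whatever interior core was never reached is
kept in the result, for the same compactness reason.

### Carving parameters

| parameter | default | meaning |
|---|---|---|
| S schedule | 16, 12, 8, 8, … mm | supervoxel spacing / layer depth per iteration, coarse→fine |
| m schedule | 40, 20, 10, 10, … HU | space-vs-luminance weight, decreasing |
| I_j, O_j | S_j and S_j/2 (O_1 = 0) | layer inner depth and outer height, tied to S |
| l0 | 400 HU | reference bone luminance (trabecular/cortical vertebral range); expert-settable |
| δ | 1/\|k\|, clamped ≤ 0.5 | per-cluster error probability |
| Q | g/64 | statistical complexity of the bone test |
| SLIC iterations | 5 | assignment/update rounds per layer |

The schedules only need their coarse-to-fine ordering; the stage is
tolerant to ±25 % perturbations (tested). The choice Q = g/64
deserves a note: b(k) shrinks like \|k\|^(−1/2), which is the right
scaling for pure noise but makes the test brittle against slight
cluster impurity when Q is large — at Q = g/2 the tolerance for a
2·10^3-voxel cluster is ~2 HU, and ten contaminated boundary voxels
are enough to veto a true bone cluster. Q = g/64 puts the tolerance
at 10–45 HU across realistic cluster sizes: robust to a handful of
stray voxels, still an order of magnitude below the bone/soft-tissue
contrast so genuinely mixed clusters keep failing.

## Fine stage: hidden Markov chain on a spiral

The coarse mask is dilated by a 10 mm Euclidean ball into the ROI,
guaranteeing the presence of both classes. The ROI is then
linearized: for each axial slice, the ROI section is peeled into
concentric perimeter rings (iterative 8-connected 2D erosion), and
the chain walks the rings outermost→innermost on one slice and
innermost→outermost on the next, each ring starting next to the
previous ring's endpoint. The alternation keeps consecutive chain
elements spatially close across slice boundaries, so the 1D
neighborhood structure the chain model sees mostly reflects true 3D
adjacency (≥ 90 % of consecutive pairs are 26-adjacent on convex
sections; raster or Hilbert scans do much worse at anatomical
boundaries, which is what motivates the spiral). Within a ring the
walk is a deterministic greedy contour-following (prefer unvisited
8-neighbors, nearest physical distance first, lexicographic ties;
jump to the nearest remaining pixel when a ring component is
exhausted): this guarantees that the path visits each ROI voxel
exactly once, so the transform is exactly invertible, which is what
the decision step requires.

The chain intensities are normalized to [0, 1] by an affine min–max
map. By default in the pipeline the endpoints are the 2 %/98 %
quantiles and values beyond them are winsorized: rare extreme
outliers — cement at ~1500 HU, air at −1000 HU — would otherwise
compress the tissue/bone contrast into a sliver of the unit interval
and the two-class mixture would lock onto the outlier instead of the
bone. Winsorizing folds extreme hyperdensities into the bone class
and extreme hypodensities into the background class, which is the
clinically desired reading (a cement-filled body is vertebra; an air
pocket is not). The quantiles are configurable; (0, 1) recovers the
pure min–max map.

The model is a two-class HMC with independent Gaussian noise: the
class sequence X over Ω = {ω0 = non-vertebra, ω1 = vertebra} is a
homogeneous Markov chain (initial law π, transitions π_ij), and
observations are conditionally independent given their own class,
y_n | x_n = ω_i ~ N(μ_i, σ_i). Posterior marginals ξ_n = p(x_n | y)
come from the forward–backward recursions with per-step
normalization (numerically safe for chains of 10^6+ elements; the
rescaling cancels exactly in ξ and in the posterior transition
probabilities). The decision is MPM — per-site argmax of ξ, the Bayes
rule for the expected per-site error — with ties to ω0.

Parameters Θ = {π_i, π_ij, μ_i, σ_i} are estimated by **SEM**:
iterate (E) forward–backward under the current Θ, (S) draw a complete
class sequence from p(x | y) through the posterior transition
probabilities, (M) re-estimate Θ by complete-data maximum likelihood.
The stochastic S-step is preferred over plain EM for robustness to
non-standard intensity distributions and local maxima. Convergence is
monitored through the disagreement fraction ε between consecutive
on-the-fly MPM classifications; the loop stops at ε < 1 % (the
classifications, unlike the raw parameters, are directly comparable
across iterations). The vertebral class is identified after
estimation as the component with the larger mean.

Numerical choices:

* σ is floored at 10⁻⁴ (normalized units) to prevent Gaussian
  collapse on noiseless data;
* π is estimated as the empirical class frequency of the sampled
  sequence rather than from the single first element (homogeneous
  chain; only the chain ends are affected);
* a degenerate S-step draw (a class vanishes) is redrawn up to three
  times, then the run stops with the last valid Θ and a warning;
* the ε test is armed only after a 3-iteration burn-in. The churn
  statistic is a proxy for parameter convergence and the proxy fails
  exactly when the data are easy: with well-separated classes the
  simple initializer already classifies perfectly, ε is ~0 from the
  first comparison, yet Θ — estimated from a posterior sample drawn
  under the crude initial parameters — is still far from its fixed
  point. Three burn-in iterations let Θ reach its fixed point on easy
  data while adding negligible cost on hard data (where ε stays
  above 1 % that long anyway);
* initialization is either μ = (0.25, 0.75), shared σ from the whole
  sequence, uniform π and π_ij ("simple", assumes [0, 1]-normalized
  input), or explicit reference parameters, e.g. calibrated on
  another vertebra of the same patient — the recommended route when
  the ROI is known to contain air and the operator prefers not to
  rely on winsorized normalization. Air is not auto-detected.

SEM default budget: at most 50 iterations; in practice well under 15
are needed. All stochastic steps are driven by a single mandatory
seed; the whole pipeline is bit-deterministic given (input, config,
seed).

## The K-means benchmark

A two-class 1D Lloyd clustering of the box intensities
(deterministic initialization at the intensity extremes, brighter
cluster = vertebra) serves as the reference the fine stage must beat.
Its known failure is air: the dark cluster locks onto −1000 HU and
soft tissue merges into the "vertebra" cluster. The HMC pipeline is
insensitive to this because the carving stage has already discarded
the background far from bone and the normalization bounds the
leverage of extreme values.

## Synthetic phantom suite

The phantom generator produces the study inputs: a schematic vertebra
(ellipsoidal body, torus arch around the canal, box-shaped spinous
process) at a bone mean of 400 HU over a 40 HU soft-tissue
background, i.i.d. Gaussian noise (default SD 30 HU), optional
anisotropic spacing, and exact ground truth by construction. Default
grid 96×96×64 at 1 mm — generated in well under a second, tall enough
for six carving iterations at the default schedule. Pathology options
mirror the clinically motivated robustness cases: hypodense lesion
(−300 HU sphere inside the body, truth unchanged), hyperdense lesion,
cementoplasty (body region set to 1500 HU, truth unchanged), air
pockets (−1000 HU spheres outside the truth), and compressed body
(axial scaling of the body primitive, truth changes).

What the phantoms exercise: the intensity statistics the method
assumes (Gaussian class-conditional noise — deliberately matching the
HMC emission model), compact non-convex geometry, anisotropy, and the
outlier regimes (air, cement). What they do not exercise: partial
volume effects, beam hardening and reconstruction artifacts,
truly textured trabecular bone, neighboring vertebrae inside the box,
and anatomically realistic shape variation. Passing the phantom suite
therefore validates the algorithmic machinery and its statistical
assumptions, not clinical performance; on real CT the reported
accuracies should be read as upper bounds.

Problem sizes used in tests and in the acceptance script (phantoms of
~0.6M voxels, chains of 2–3·10^5 elements, SEM recovery at N = 5·10^4
over 20 seeds) were chosen so the full suite runs on a single CPU in
a few minutes while keeping every cluster/chain statistic in its
asymptotic regime.

## Known limitations

* l0 is an expert-provided constant; no automatic histogram
  calibration. A grossly wrong l0 (≫ b(k) away from true bone) empties
  the carving and the pipeline returns an empty mask with a warning.
* The interiority predicate accepts anything between accepted bone
  and the remaining-volume centre; with an object far off-centre in
  its box, the coarse mask can bulge toward the centre on one flank.
  The fine stage re-discriminates those voxels, so the final mask is
  unaffected, but the intermediate coarse mask is not a tight
  segmentation.
* The vertebral-body interior can be excluded on real data when
  trabecular bone reads much darker than cortical bone (the fine
  stage is purely intensity-driven); an optional hole-filling
  post-process exists but is off by default.
* Two classes only; no HMRF, no EM variant, no Hilbert/raster
  linearizations, no automatic bounding-box detection, no DICOM
  series assembly (NIfTI/MetaImage only).
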