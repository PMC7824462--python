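# Methods

This note documents the models implemented in `lamap`, the defaults and the
numerical choices, and what the synthetic phantom does and does not emulate.

## Model overview

The detector treats landmark localization as two-stage MAP estimation on a
contrast-enhanced CT volume. Stage one finds the two reference vessels
(ascending and descending aorta) whose axial cross-sections are large and
near-circular; stage two localizes the five targets (LSPV, LIPV, RSPV,
RIPV, LAA) purely through their geometric relation to the fixed reference
axes plus a contrast-intensity likelihood. The factorization assumes the
reference posterior is sharply peaked — once the aorta pair is committed,
its uncertainty is ignored downstream.

All geometry is computed in physical millimetres; voxel indices are 0-based
with `position = origin + index * spacing`, axial slice = fixed z index.
Volumes are assumed axis-aligned (no orientation-matrix handling); the
phantom defines its own axes and real-data use assumes standard axial
orientation.

## Intensity adaptation

Voxels at or below 0 HU (air, lung, most fat) are discarded; the remaining
values are partitioned by two-cluster 1-D k-means under the within-cluster
sum-of-squares objective. The implementation is deterministic: centers
start at the 25th/75th percentiles of the positive values and Lloyd
iterations run to a 1e-6 HU tolerance (max 300). In one dimension this
ordered initialization converges to the exhaustive-breakpoint WCSS optimum
on every dataset we test against an explicit oracle. Volumes above 1e7
voxels are clustered on a 1-HU-binned histogram (weighted k-means), which
agrees with the raw-sample path to within the bin width at bounded memory.
A degenerate cluster deviation is floored at 1 HU so the derived thresholds
and the downstream intensity likelihood stay finite on noiseless phantoms.

The candidate mask keeps voxels in `[I1, I2]`, `I1 = min(muB + sigmaB,
muF - sigmaF)`, `I2 = muF + sigmaF`, inclusive at both ends. Note a
structural property of this window: whenever the two classes are well
separated the lower bound sits at exactly one background standard deviation
above the background mean, so roughly the upper sixth of the background
class is always inside the mask regardless of how small the noise is. The
consequences for candidate extraction are handled below.

## Reference detection

Per axial slice the mask is labeled with 8-connected component analysis;
components smaller than 50 mm² (or 3 pixels) are dropped — aortic
cross-sections are an order of magnitude larger. Each component's isotropy
ratio r = λ1/λ2 comes from the population (ddof = 0) covariance of its
pixel coordinates in mm; r = 1 for circles, 0 for collinear sets. Every
*ordered* pair (i, j) is scored by

    -(|1-r_i|^2 + |1-r_j|^2)/sigma_r^2
    - |1 - delta_ij/delta_bar|^2/sigma_delta^2
    - |1 - theta_ij/theta_bar|^2/sigma_theta^2

with theta the angle of the directed i→j vector against +x, folded to
[0°, 360°). The ordering itself disambiguates AA from DA: the reversed pair
differs by 180° in theta and is penalized by the angle prior (with
sigma_theta = 0.011 normalized, a 180° flip is astronomically unlikely), so
no separate anterior/posterior heuristic is needed. Slices with fewer than
two surviving regions are skipped. sigma_r defaults to 0.1 — one sigma of
isotropy deviation corresponds to a visibly elliptical region; the value is
configurable and not part of the measured prior table.

Per-slice winning centroids are fitted with one 3D line per vessel:
ordinary least squares of x(z), y(z) with iterative outlier rejection
(drop slices with in-plane residual > 2.5 SD, refit, at most 5 rounds,
minimum 3 accepted slices). Axis directions are normalized with positive
z-component. Downstream, reference centroids at any slice are read off the
fitted axes rather than the raw per-slice detections, which makes target
scoring robust on slices where the pair search failed.

## Target similarity and its invariance

For a pixel at in-plane distances d_A, d_D from the two reference centroids
with inter-reference distance d_AD, each label k is scored by first
rescaling the measured distances by delta_bar/d_AD — mapping the patient
onto the mean reference separation — and then evaluating the learned
per-label Gaussians:

    f_k = -|d_A * delta_bar/d_AD - mu_kA|^2 / sigma_kA^2
          -|d_D * delta_bar/d_AD - mu_kD|^2 / sigma_kD^2.

Each term is a function of the dimensionless ratios d_A/d_AD and d_D/d_AD
only, which makes the map *strictly* invariant under joint rotation,
translation and uniform scaling of references and query point — the
property the method's flexibility rests on, and one we assert over
randomized similarity transforms. An alternative normalization that divides
the distances by the learned means and the deviations by coefficients of
variation produces the same zero locus and agrees exactly when
d_AD = delta_bar, but retains a residual quadratic dependence on overall
scale; we use the strictly invariant form.

The locus f_k = 0 is the intersection of two circles and has a mirror
solution across the AA–DA axis. Pixels whose perpendicular component
relative to the directed AA→DA vector (measured from the reference
midpoint) has the wrong sign are masked to −inf. All five landmarks lie on
the left-atrial side, so the per-label side signs default to +1; they are
re-estimated by majority vote during prior learning.

## Candidate extraction and the despeckle step

A voxel enters the 3D candidate set iff `max_k f_k >= alpha` and it lies in
the intensity candidate mask. `alpha` defaults to −8 in log units, i.e. a
combined two-standard-score deviation per distance term; it is
configurable. The selected set then receives **one binary opening with the
6-connected cross** before 26-connected component analysis. This step is
load-bearing: as noted above, the mask window intrinsically admits the
upper ~16% tail of the background class, and 16% voxel-wise speckle exceeds
the 3D site-percolation threshold of the 26-neighborhood (~0.097) — without
the opening, background speckle inside the similarity band chains into a
single arbitrarily large component that swallows genuine targets. The
opening annihilates voxel-scale speckle while leaving solid,
landmark-sized objects essentially unchanged. Components with fewer than
10 voxels are dropped; each surviving candidate records its centroid (mm),
mean intensity, peak similarity and the set of labels whose maps support it.

## Assignment search

The five labels are assigned to distinct candidates maximizing

    sum_k -|muF - I_k|^2/sigmaF^2  +  sum_{i<j} -|mu_ij - d_ij|^2/sigma_ij^2,

with d_ij the 3D centroid distance of the assigned pair. Label k may only
take candidates whose f_k supported them; candidates are pre-pruned to the
20 highest peak similarities. The search is exact branch-and-bound: since
every geometry term is non-positive, the partial score plus the best
remaining intensity terms is a valid upper bound. Exact ties break on the
lexicographically smallest candidate-index tuple for determinism. With at
most 8 candidates the result provably equals full enumeration (asserted in
tests). Fewer than five candidates, or a label with no supporting
candidate, raises an error naming the missing labels — on real data this is
a missed detection, counted as a false negative.

The pairwise means mu_ij are not part of the measured per-reference table;
the shipped defaults are derived once by trilaterating each label at its
mean distances in a canonical frame (AA at the origin, DA at
(delta_bar, 0)) and measuring the pairwise separations, with a common
sigma_ij = 8 mm. Prior learning can override them the same way from
re-estimated means.

## Prior learning

Annotated cases supply reference centroids (at an annotator-chosen slice)
and labeled landmark positions in mm. Per case we measure delta, theta
(ordered AA→DA, degrees), each landmark's in-plane distances to both
references and its side sign; across cases, means and (n−1)-denominator
standard deviations are estimated, with the reference deviations stored
normalized by their means. Degenerate deviations are floored at 0.5 mm.
Estimation requires at least two samples per quantity and names the
offending quantity otherwise. With samples drawn from the defaults, the
learned means converge as expected (within ~3 sigma/sqrt(n); at n = 200
the reference distance lands within a millimetre).

## The phantom: what it emulates, what it does not

The generator renders, at 1 mm isotropic resolution in a 160³ volume
(desk-scale; clinical volumes are 512² × ~300 at 0.26–0.48 mm, and the
geometry is mm-true so resolution is a fidelity, not correctness,
parameter):

* a soft-tissue background at muB = 80 HU and contrast foreground at
  muF = 400 HU, each with class-conditional Gaussian noise (sigmaB = 20,
  sigmaF = 50 HU) — reproducing the bimodal positive-HU histogram the
  intensity stage adapts to; an optional correlation length smooths the
  noise field, and `noiseless()` zeroes the spread for exactness tests;
* two vertical cylinders (radii 14 and 10 mm) whose in-plane centers
  realize the configured (delta, theta);
* five spherical targets (radius 6 mm) trilaterated at configured or
  prior-drawn distances on the configured side, at a configurable slice;
* decoy blobs (default 3) with contrast-like intensity whose (d_A, d_D)
  are rejection-sampled to violate every label's 2-sigma distance band —
  geometrically wrong but photometrically plausible, stressing the
  assignment prior rather than the threshold.

Feasibility (circle intersection, volume extent, non-overlap of targets
with each other and with the cylinders) is checked before any voxel is
written; generation is bit-reproducible from (spec, seed), and the ground
truth records per-label voxel masks whose realized distances match the
request to within half a voxel.

Deliberate simplifications: straight vertical aortae (no arch curvature or
tilt), spherical targets, no beam hardening, partial-volume or motion
artifacts, no surrounding anatomy (lungs, bone, myocardium). Passing on
phantoms therefore demonstrates the geometric and photometric logic of the
pipeline — not robustness to real anatomical variation, abnormal
positioning (e.g. situs inversus), or scanner artifacts. Because targets
are drawn from the same Gaussians the priors encode, a drawn case can land
beyond the similarity threshold's ~2.8 combined standard scores
(probability ≈ 2% per label) and legitimately fail detection, mirroring
the imperfect per-label detection rates seen on clinical data.

## Evaluation

A predicted landmark is a true positive iff the voxel containing its
position belongs to the ground-truth region for that label — a set
membership criterion, not a distance cut. TPR = TP/(TP+FN) per label; the
overall figure is the arithmetic mean of per-label TPRs. A `tolerance_mm`
option additionally reports centroid-distance hits for diagnostics but
never alters the TPR.

## Problem sizes used in the shipped checks

The test suite runs most end-to-end checks on 40-slice phantoms (identical
in-plane geometry); the reproduction script uses the full default phantom:
50 cases for the reference-detection rate, 200 annotation cases for prior
recovery, and 20 full detections for the landmark-distance measurement.
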