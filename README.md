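# lamap — left-atrial landmark localization in cardiac CT

`lamap` simultaneously localizes five left-atrial landmarks — the four
pulmonary vein ostia (LSPV, LIPV, RSPV, RIPV) and the left atrial appendage
(LAA) — in contrast-enhanced cardiac CT volumes. These landmarks are needed
for atrial-fibrillation ablation planning and LAA occlusion-device sizing,
but they have variable shapes and no crisp boundaries, so they are hard to
detect one at a time. `lamap` instead exploits the stable *geometric*
relationship of all five landmarks to two easy-to-find reference vessels:
the ascending (AA) and descending (DA) aorta, which appear as large,
near-circular cross-sections in every axial slice.

The package is aimed at medical-image-analysis researchers. It ships a
synthetic phantom generator that reproduces the geometry and intensity
structure the method relies on, so every stage is testable without clinical
data.

## Method

Detection is a two-stage MAP estimation. Writing `C1..Cm` for the targets
and `Cm+1, Cm+2` for the references, the posterior factorizes so that the
references are found first,

    argmax  L(I | C_{m+1}, C_{m+2}) + L(C_{m+1}, C_{m+2}),

and the targets are then found conditioned on the fixed reference axes,

    argmax  L(I | C_1..C_m) + L(C_1..C_m | C*_{m+1}, C*_{m+2}).

**Intensity adaptation.** Contrast density varies per scan, so voxels above
0 HU are split by 1-D k-means (k = 2, WCSS objective) into background
(μB, σB) and foreground (μF, σF); the candidate mask keeps voxels in
[I1, I2] with I1 = min(μB + σB, μF − σF), I2 = μF + σF.

**Reference detection.** Per axial slice, connected components of the mask
are scored by shape — the eigenvalue ratio r = λ1/λ2 of the coordinate
covariance is ≈ 1 for circles — giving −(|1−r_AA|² + |1−r_DA|²)/σr², plus a
geometric prior on the centroid pair: −|1−δ/δ̄|²/σδ² − |1−θ/θ̄|²/σθ², where
δ is the AA→DA distance and θ its angle to the x-axis (δ̄ = 81.6 mm,
θ̄ = 66.9°). The per-slice winning pairs are fitted with robust 3D lines,
one axis per vessel.

**Target localization.** Every pixel gets a per-label similarity from its
distances d_AA, d_DA to the reference axes and the inter-reference distance
d_AD:

    f_k = −|d_AA·δ̄/d_AD − μ_{k,AA}|²/σ²_{k,AA} − |d_DA·δ̄/d_AD − μ_{k,DA}|²/σ²_{k,DA},

which depends only on the ratios d_AA/d_AD and d_DA/d_AD and is therefore
invariant to rotation, translation and uniform scaling of the anatomy. The
mirror solution across the AA–DA axis is masked out by the side sign of the
target direction. Suprathreshold voxels (max_k f_k ≥ α) inside the
candidate mask form 3D candidate objects; the five labels are assigned to
distinct candidates by maximizing an intensity likelihood
−|μF − I_k|²/σF² plus a complete-graph prior over all ten pairwise
inter-landmark distances, −Σ |μ_{i,j} − δ_{i,j}|²/σ²_{i,j} (exact
branch-and-bound search).

The per-label distance priors (μ, σ to each reference, in mm) are the
measured defaults shipped with the package and can be re-estimated from
annotated cases with `lamap.learn_priors` / `lamap learn-priors`.

## Worked example

```python
import numpy as np
import lamap

volume, truth = lamap.generate_phantom(lamap.PhantomSpec(), seed=7)
out = lamap.detect_landmarks(volume)
for r in out.results:
    err = np.linalg.norm(np.asarray(r.position_mm)
                         - np.asarray(truth.target_centers_mm[r.label]))
    print(r.label, r.position_mm, round(err, 2))
```

Running `python examples/02_detect_landmarks.py` (the same computation with
per-stage reporting) prints:

```
intensity model: muB = 80.0, muF = 400.3 HU (mask window [100, 450] HU)
reference axes: delta = 81.69 mm (true 81.60), theta = 66.93 deg (true 66.90)
5 candidate objects; MAP score -0.707 = intensity -0.703 + geometry -0.004
label   detected position (mm)      error (mm)
  LSPV  (  36.7,   89.1,   79.3)    0.35
  LIPV  (  56.3,  104.7,   79.3)    0.27
  RSPV  (  15.1,   52.0,   79.6)    0.26
  RIPV  (  21.4,   82.0,   79.4)    0.11
  LAA   (  25.4,   67.4,   79.3)    0.25
point-in-region TPR: 1.00
```

The intensity model recovers the phantom's generating HU parameters, the
fitted reference axes match the true cylinder geometry to a tenth of a
millimetre, and all five landmarks land inside their ground-truth regions
(sub-voxel centroid error). A MAP score near 0 means both the contrast
likelihood and the pairwise-distance prior are satisfied almost exactly;
the decoy blobs score orders of magnitude lower. The other scripts in
`examples/` demonstrate phantom generation and prior learning.

A command-line interface mirrors the library:

```sh
lamap phantom --seed 1 --out vol.nii.gz --truth truth.json --truth-labels labels.nii.gz
lamap detect vol.nii.gz --out landmarks.json
lamap learn-priors annotations/ --out priors.yaml
lamap eval --pred preds/ --truth truths/ --out report.json
```

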