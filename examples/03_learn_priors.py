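"""Estimate the geometric prior table from synthetic annotated geometries.

Draws 200 annotated cases from the default prior's Gaussians, measures each
case's reference separation/angle and per-landmark distances, and re-estimates
the prior parameters — demonstrating the learning loop that would otherwise
run on manually annotated clinical cases.
"""

import numpy as np

import lamap
from lamap.phantom import generate_annotation_cases

prior = lamap.default_priors()
cases = generate_annotation_cases(prior, 200, np.random.default_rng(7))
samples = lamap.measure_geometry(cases)
learned = lamap.estimate_params(samples)

print(f"cases measured: {len(samples)}")
print(f"reference distance: learned {learned.delta_bar:.2f} mm "
      f"(configured {prior.delta_bar} mm)")
print(f"reference angle:    learned {learned.theta_bar:.2f} deg "
      f"(configured {prior.theta_bar} deg)")
print("per-label mean distances to AA, mm (learned vs configured):")
for label in lamap.LANDMARK_LABELS:
    mu_hat, sigma_hat = learned.distance_params(label, "AA")
    mu, sigma = prior.distance_params(label, "AA")
    print(f"  {label:4s}: {mu_hat:6.2f} +- {sigma_hat:5.2f}   vs {mu:6.2f} +- {sigma:5.2f}")
# With n = 200 the means land well within a millimetre of the generating
# values; at the clinical training size (n = 8) expect several mm of scatter.
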