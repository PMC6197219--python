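"""Non-rigid motion correction of a deformed synthetic movie.

Estimates per-frame displacement fields on the structural channel, compares
them with the generator's ground truth, and shows that registration sharpens
the temporal mean image.
"""

import numpy as np

from vnc2p import (
    SyntheticConfig,
    compute_matches,
    detect_artifacts,
    estimate_motion,
    make_ground_truth,
    make_structural_template,
    registration_quality,
    render_movie,
    warp_frame,
)

cfg = SyntheticConfig(rng_seed=1, n_frames=12, deformation_amplitude=3.0, noise_sd=20.0)
template = make_structural_template(cfg)
truth = make_ground_truth(cfg)
movie = render_movie(template, truth.true_fields, truth, cfg)

ref = movie.structural[0]
registered = [ref]
errors = []
for t in range(1, movie.n_frames):
    matches = compute_matches(ref, movie.structural[t])
    result = estimate_motion(ref, movie.structural[t], matches)
    registered.append(warp_frame(movie.structural[t], result.field))
    epe = np.sqrt(((result.field - truth.true_fields[t]) ** 2).sum(-1)).mean()
    errors.append(epe)
    report = detect_artifacts(result.field)
    assert not report.flagged  # no divergence sinks on well-posed frames

q_reg = registration_quality(np.stack(registered))
q_raw = registration_quality(movie.structural)
print(f"mean endpoint error vs ground truth: {np.mean(errors):.3f} px "
      "(sub-pixel accuracy; 0 would be perfect)")
print(f"temporal-mean sharpness: registered {q_reg:.1f} vs unregistered {q_raw:.1f} "
      "(higher = structures superimpose consistently)")
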