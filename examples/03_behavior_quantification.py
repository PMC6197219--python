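"""From raw ball rotations and behavior video to calibrated behavior labels.

Converts optic flow (rot/s) to physical velocities, segments locomotor bouts,
and annotates walking/grooming from the synthetic behavior video.
"""

from vnc2p import (
    AnnotationParams,
    OpticFlowTrace,
    SyntheticConfig,
    annotate_video,
    convert_optic_flow,
    make_behavior_frames,
    make_ground_truth,
    segment_bouts,
)
from vnc2p.synthetic import default_video_rois, make_optic_flow

cfg = SyntheticConfig(
    rng_seed=2, n_frames=200, frame_rate=8.0,
    behavior_schedule=[("walk_fwd", 3.0, 7.0), ("walk_bwd", 10.0, 12.0),
                       ("groom", 15.0, 19.0)],
)
truth = make_ground_truth(cfg)

t, ap, ml, yaw = make_optic_flow(truth, cfg)
velocity = convert_optic_flow(OpticFlowTrace(t, ap, ml, yaw))
seg = segment_bouts(velocity)
print(f"velocity peaks: forward {velocity.v_forward.max():.1f} mm/s, "
      f"backward {velocity.v_forward.min():.1f} mm/s")
print(f"{len(seg.bouts)} bouts detected; {seg.percent_time_walking:.1f}% of time walking")
for label, start, end in seg.bouts[:4]:
    print(f"  {label:9s} {start:6.2f}-{end:6.2f} s")

frames = make_behavior_frames(truth, cfg)
roi_walk, roi_groom = default_video_rois(cfg)
s_w, s_g = annotate_video(frames, AnnotationParams(roi_walk=roi_walk, roi_groom=roi_groom))
fps = cfg.video_rate
print(f"video annotation: walking {s_w.sum() / fps:.1f} s "
      f"(scheduled 6.0 s), grooming {s_g.sum() / fps:.1f} s (scheduled 4.0 s)")
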