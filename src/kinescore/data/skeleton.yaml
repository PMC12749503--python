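# Default planar skeleton used by the synthetic-motion generator.
# Segment lengths are standard anthropometric ratios expressed as fractions
# of stature; the stature is given in pixels and the root (mid-hip) as a
# fraction of the frame.  Rest angles are the joint triplet angles of the
# neutral standing pose, in degrees.  rotation_sign fixes the in-plane
# rotation direction of each body side's driven segments.
stature_px: 600
root: [0.5, 0.52]
proportions:
  hip_half_width: 0.05
  shoulder_half_width: 0.10
  trunk: 0.30
  neck_to_nose: 0.10
  head_radius: 0.04
  upper_arm: 0.17
  forearm: 0.16
  hand: 0.08
  thigh: 0.245
  shank: 0.246
  foot: 0.12
  heel: 0.05
rest_angles:
  shoulder: 15.0
  elbow: 170.0
  hip_sagittal: 175.0
  hip_frontal: 95.0
  knee: 175.0
rotation_sign:
  left: 1
  right: -1
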