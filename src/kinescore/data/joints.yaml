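# Joint triplet table: (proximal, vertex, distal) landmark indices in the
# standard 33-landmark pose topology.  The vertex is the articulating joint;
# the angle is measured between the vertex->proximal and vertex->distal limb
# vectors.  Editable: clinicians can redefine triplets or add joints.
#
# Index map used: 11/12 shoulders, 13/14 elbows, 15/16 wrists,
# 23/24 hips, 25/26 knees, 27/28 ankles (left/right).
left_elbow:        {triplet: [11, 13, 15], plane: sagittal}
right_elbow:       {triplet: [12, 14, 16], plane: sagittal}
left_shoulder:     {triplet: [23, 11, 13], plane: frontal}
right_shoulder:    {triplet: [24, 12, 14], plane: frontal}
left_hip_sagittal: {triplet: [11, 23, 25], plane: sagittal}
right_hip_sagittal: {triplet: [12, 24, 26], plane: sagittal}
left_hip_frontal:  {triplet: [24, 23, 25], plane: frontal}
right_hip_frontal: {triplet: [23, 24, 26], plane: frontal}
left_knee:         {triplet: [23, 25, 27], plane: sagittal}
right_knee:        {triplet: [24, 26, 28], plane: sagittal}
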