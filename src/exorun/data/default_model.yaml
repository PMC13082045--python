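# Generic planar running model: 20 generalized coordinates, sagittal-plane
# kinematic tree rooted at a 3-DOF (tx, ty, tilt) pelvis-ground joint plus
# out-of-plane pelvis/lumbar rotations that are locked by default.
#
# Anthropometry: generic height 1.80 m / mass 75.1654 kg, segment masses and
# inertias follow standard regression tables (gait2392-flavored, arms split
# out of the torso so they can be actuated separately). Scaling to a subject
# is linear in height for lengths, linear in mass for masses, mass*length^2
# for inertias.
#
# Conventions: x forward, y up, right-handed rotation about +z (out of the
# screen, pointing left). Hip/shoulder/elbow flexion positive, knee flexion
# negative, ankle/MTP dorsiflexion positive. SI units, radians.
generic_height_m: 1.80
generic_mass_kg: 75.1654
gravity_m_s2: 9.81

coordinates:
  # name, motion type, locked flag (out-of-sagittal-plane DOFs locked)
  - {name: pelvis_tilt, kind: rotational, locked: false}
  - {name: pelvis_list, kind: rotational, locked: true}
  - {name: pelvis_rotation, kind: rotational, locked: true}
  - {name: pelvis_tx, kind: translational, locked: false}
  - {name: pelvis_ty, kind: translational, locked: false}
  - {name: lumbar_extension, kind: rotational, locked: false}
  - {name: lumbar_bending, kind: rotational, locked: true}
  - {name: lumbar_rotation, kind: rotational, locked: true}
  - {name: hip_flexion_r, kind: rotational, locked: false}
  - {name: knee_angle_r, kind: rotational, locked: false}
  - {name: ankle_angle_r, kind: rotational, locked: false}
  - {name: mtp_angle_r, kind: rotational, locked: false}
  - {name: hip_flexion_l, kind: rotational, locked: false}
  - {name: knee_angle_l, kind: rotational, locked: false}
  - {name: ankle_angle_l, kind: rotational, locked: false}
  - {name: mtp_angle_l, kind: rotational, locked: false}
  - {name: arm_flex_r, kind: rotational, locked: false}
  - {name: elbow_flex_r, kind: rotational, locked: false}
  - {name: arm_flex_l, kind: rotational, locked: false}
  - {name: elbow_flex_l, kind: rotational, locked: false}

segments:
  pelvis:    {mass: 11.777,  inertia: 0.1028, length: 0.13,  com: [-0.0707, 0.0]}
  torso:     {mass: 26.9724, inertia: 1.2045, length: 0.52,  com: [-0.03, 0.30]}
  thigh_r:   {mass: 9.3014,  inertia: 0.1339, length: 0.46,  com: [0.0, -0.17]}
  shank_r:   {mass: 3.7075,  inertia: 0.0504, length: 0.4703, com: [0.0, -0.1867]}
  calcn_r:   {mass: 1.35,    inertia: 0.0041, length: 0.25,  com: [0.05, -0.02]}
  toes_r:    {mass: 0.2166,  inertia: 0.0002, length: 0.07,  com: [0.021, -0.002]}
  humerus_r: {mass: 2.0325,  inertia: 0.0133, length: 0.33,  com: [0.0, -0.164]}
  forearm_r: {mass: 1.6,     inertia: 0.0190, length: 0.29,  com: [0.0, -0.12]}
  thigh_l:   {mass: 9.3014,  inertia: 0.1339, length: 0.46,  com: [0.0, -0.17]}
  shank_l:   {mass: 3.7075,  inertia: 0.0504, length: 0.4703, com: [0.0, -0.1867]}
  calcn_l:   {mass: 1.35,    inertia: 0.0041, length: 0.25,  com: [0.05, -0.02]}
  toes_l:    {mass: 0.2166,  inertia: 0.0002, length: 0.07,  com: [0.021, -0.002]}
  humerus_l: {mass: 2.0325,  inertia: 0.0133, length: 0.33,  com: [0.0, -0.164]}
  forearm_l: {mass: 1.6,     inertia: 0.0190, length: 0.29,  com: [0.0, -0.12]}

# Planar kinematic tree. The pelvis-ground joint is expanded into three
# stacked primitive joints (tx, ty, tilt) through massless virtual links.
joints:
  - {name: ground_pelvis_tx, type: translational, parent: ground, child: _v1,
     coordinate: pelvis_tx, axis: [1.0, 0.0], location: [0.0, 0.0]}
  - {name: ground_pelvis_ty, type: translational, parent: _v1, child: _v2,
     coordinate: pelvis_ty, axis: [0.0, 1.0], location: [0.0, 0.0]}
  - {name: ground_pelvis_tilt, type: rotational, parent: _v2, child: pelvis,
     coordinate: pelvis_tilt, location: [0.0, 0.0]}
  - {name: lumbar, type: rotational, parent: pelvis, child: torso,
     coordinate: lumbar_extension, location: [-0.03, 0.0815]}
  - {name: hip_r, type: rotational, parent: pelvis, child: thigh_r,
     coordinate: hip_flexion_r, location: [-0.0707, -0.0661]}
  - {name: knee_r, type: rotational, parent: thigh_r, child: shank_r,
     coordinate: knee_angle_r, location: [0.0, -0.46]}
  - {name: ankle_r, type: rotational, parent: shank_r, child: calcn_r,
     coordinate: ankle_angle_r, location: [0.0, -0.4703]}
  - {name: mtp_r, type: rotational, parent: calcn_r, child: toes_r,
     coordinate: mtp_angle_r, location: [0.17, -0.045]}
  - {name: hip_l, type: rotational, parent: pelvis, child: thigh_l,
     coordinate: hip_flexion_l, location: [-0.0707, -0.0661]}
  - {name: knee_l, type: rotational, parent: thigh_l, child: shank_l,
     coordinate: knee_angle_l, location: [0.0, -0.46]}
  - {name: ankle_l, type: rotational, parent: shank_l, child: calcn_l,
     coordinate: ankle_angle_l, location: [0.0, -0.4703]}
  - {name: mtp_l, type: rotational, parent: calcn_l, child: toes_l,
     coordinate: mtp_angle_l, location: [0.17, -0.045]}
  - {name: shoulder_r, type: rotational, parent: torso, child: humerus_r,
     coordinate: arm_flex_r, location: [0.003, 0.355]}
  - {name: elbow_r, type: rotational, parent: humerus_r, child: forearm_r,
     coordinate: elbow_flex_r, location: [0.0, -0.30]}
  - {name: shoulder_l, type: rotational, parent: torso, child: humerus_l,
     coordinate: arm_flex_l, location: [0.003, 0.355]}
  - {name: elbow_l, type: rotational, parent: humerus_l, child: forearm_l,
     coordinate: elbow_flex_l, location: [0.0, -0.30]}

# Named points expressed in a segment frame, with a constant mediolateral
# (z) offset so 3-D distances (exotendon) and marker export are defined.
# Contact sphere centers: one heel, one forefoot, two at the
# metatarsophalangeal joint (placement near the MTP joint; the generic model
# descriptions are ambiguous about "rearfoot" here).
points:
  contact_heel_r:     {segment: calcn_r, offset: [-0.035, -0.040], z: -0.125}
  contact_forefoot_r: {segment: calcn_r, offset: [0.100, -0.040], z: -0.125}
  contact_mtp1_r:     {segment: calcn_r, offset: [0.155, -0.040], z: -0.125}
  contact_mtp2_r:     {segment: toes_r, offset: [0.010, 0.003], z: -0.125}
  contact_heel_l:     {segment: calcn_l, offset: [-0.035, -0.040], z: 0.125}
  contact_forefoot_l: {segment: calcn_l, offset: [0.100, -0.040], z: 0.125}
  contact_mtp1_l:     {segment: calcn_l, offset: [0.155, -0.040], z: 0.125}
  contact_mtp2_l:     {segment: toes_l, offset: [0.010, 0.003], z: 0.125}
  anchor_r:           {segment: calcn_r, offset: [-0.045, -0.025], z: -0.125}
  anchor_l:           {segment: calcn_l, offset: [-0.045, -0.025], z: 0.125}

# Passive rotational spring-dampers representing ligaments / soft tissue at
# the lumbar and metatarsophalangeal joints: tau = -k*q - c*qdot.
passive_joint_forces:
  lumbar_extension: {stiffness: 10.0, damping: 1.0}
  mtp_angle_r: {stiffness: 25.0, damping: 0.40}
  mtp_angle_l: {stiffness: 25.0, damping: 0.40}

# Leg length for slack-length conversion is thigh + shank length; the
# scaled subject model gives 0.92 m.
leg_length_segments: [thigh_r, shank_r]
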