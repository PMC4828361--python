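# Default full-body model: 15 rigid segments, 42 distinct marker labels,
# and the nine studied muscles of the kick/pitch analyses.
#
# Conventions: right-handed, X lateral (subject's right), Y anterior, Z up,
# millimetres, 0-based frames. Segment-local frames are aligned with the
# global frame in the neutral standing posture; each origin sits at the
# segment's proximal joint centre. Dimensions describe a 1.70 m reference
# body.
#
# Markers shared between adjacent segments (xSHO, xELB, xWRA/xWRB) sit at a
# joint centre or on the wrist flexion axis, so both segments' templates map
# them to the same global point under the motions the presets prescribe.
#
# Muscle attachment coordinates are plausible fixtures in segment-local mm,
# not anatomical ground truth.

coordinate_convention:
  handedness: right
  up_axis: z
  units: mm
  frame_indexing: 0

segments:
  pelvis:                       # lower trunk; tree root
    parent: null
    origin_in_parent: [0.0, 0.0, 950.0]
    euler_sequence: XYZ
    markers:
      LASI: [-110.0, 80.0, 20.0]
      RASI: [110.0, 80.0, 20.0]
      LPSI: [-50.0, -90.0, 30.0]
      RPSI: [50.0, -90.0, 30.0]
  upper_trunk:
    parent: pelvis
    joint: spine
    origin_in_parent: [0.0, 0.0, 150.0]
    markers:
      CLAV: [0.0, 80.0, 320.0]
      C7: [0.0, -70.0, 340.0]
      LSHO: [-190.0, 0.0, 300.0]    # left shoulder joint centre
      RSHO: [190.0, 0.0, 300.0]     # right shoulder joint centre
  head:
    parent: upper_trunk
    joint: neck
    origin_in_parent: [0.0, 0.0, 350.0]
    markers:
      LFHD: [-80.0, 90.0, 150.0]
      RFHD: [80.0, 90.0, 150.0]
      LBHD: [-80.0, -90.0, 140.0]
      RBHD: [80.0, -90.0, 140.0]
  upper_arm_r:
    parent: upper_trunk
    joint: shoulder_r
    origin_in_parent: [190.0, 0.0, 300.0]
    markers:
      RSHO: [0.0, 0.0, 0.0]         # shared with upper_trunk (joint centre)
      RUPA: [45.0, 15.0, -160.0]
      RELB: [0.0, 0.0, -300.0]      # elbow joint centre
  upper_arm_l:
    parent: upper_trunk
    joint: shoulder_l
    origin_in_parent: [-190.0, 0.0, 300.0]
    markers:
      LSHO: [0.0, 0.0, 0.0]
      LUPA: [-45.0, 15.0, -160.0]
      LELB: [0.0, 0.0, -300.0]
  forearm_r:
    parent: upper_arm_r
    joint: elbow_r
    origin_in_parent: [0.0, 0.0, -300.0]
    markers:
      RELB: [0.0, 0.0, 0.0]         # shared with upper_arm_r (joint centre)
      RFRM: [30.0, 15.0, -130.0]
      RWRA: [35.0, 0.0, -250.0]     # on the wrist flexion axis
      RWRB: [-35.0, 0.0, -250.0]
  forearm_l:
    parent: upper_arm_l
    joint: elbow_l
    origin_in_parent: [0.0, 0.0, -300.0]
    markers:
      LELB: [0.0, 0.0, 0.0]
      LFRM: [-30.0, 15.0, -130.0]
      LWRA: [-35.0, 0.0, -250.0]
      LWRB: [35.0, 0.0, -250.0]
  hand_r:
    parent: forearm_r
    joint: wrist_r
    origin_in_parent: [0.0, 0.0, -250.0]
    markers:
      RWRA: [35.0, 0.0, 0.0]        # shared with forearm_r
      RWRB: [-35.0, 0.0, 0.0]
      RFIN: [0.0, 15.0, -80.0]
  hand_l:
    parent: forearm_l
    joint: wrist_l
    origin_in_parent: [0.0, 0.0, -250.0]
    markers:
      LWRA: [-35.0, 0.0, 0.0]
      LWRB: [35.0, 0.0, 0.0]
      LFIN: [0.0, 15.0, -80.0]
  thigh_r:
    parent: pelvis
    joint: hip_r
    origin_in_parent: [90.0, 0.0, -50.0]
    markers:
      RTHI: [70.0, 10.0, -200.0]
      RTHA: [20.0, 70.0, -180.0]
      RKNE: [60.0, 0.0, -420.0]
  thigh_l:
    parent: pelvis
    joint: hip_l
    origin_in_parent: [-90.0, 0.0, -50.0]
    markers:
      LTHI: [-70.0, 10.0, -200.0]
      LTHA: [-20.0, 70.0, -180.0]
      LKNE: [-60.0, 0.0, -420.0]
  shank_r:
    parent: thigh_r
    joint: knee_r
    origin_in_parent: [0.0, 0.0, -420.0]
    markers:
      RTIB: [55.0, 10.0, -40.0]
      RSHK: [45.0, 15.0, -200.0]
      RANK: [40.0, 0.0, -400.0]
  shank_l:
    parent: thigh_l
    joint: knee_l
    origin_in_parent: [0.0, 0.0, -420.0]
    markers:
      LTIB: [-55.0, 10.0, -40.0]
      LSHK: [-45.0, 15.0, -200.0]
      LANK: [-40.0, 0.0, -400.0]
  foot_r:
    parent: shank_r
    joint: ankle_r
    origin_in_parent: [0.0, 0.0, -400.0]
    markers:
      RHEE: [0.0, -60.0, -40.0]
      RMT5: [35.0, 120.0, -70.0]
      RTOE: [0.0, 170.0, -60.0]
  foot_l:
    parent: shank_l
    joint: ankle_l
    origin_in_parent: [0.0, 0.0, -400.0]
    markers:
      LHEE: [0.0, -60.0, -40.0]
      LMT5: [-35.0, 120.0, -70.0]
      LTOE: [0.0, 170.0, -60.0]

# Kick-side (right) leg muscles plus the two pitching trunk muscles.
muscles:
  rectus_femoris:
    points:
      - {segment: pelvis, position: [95.0, 70.0, -20.0]}
      - {segment: thigh_r, position: [20.0, 60.0, -400.0]}
      - {segment: shank_r, position: [0.0, 45.0, -60.0]}
  vastus_lateralis:
    points:
      - {segment: thigh_r, position: [60.0, 10.0, -100.0]}
      - {segment: thigh_r, position: [30.0, 50.0, -400.0]}
      - {segment: shank_r, position: [0.0, 45.0, -60.0]}
  biceps_femoris:
    points:
      - {segment: pelvis, position: [55.0, -40.0, -80.0]}
      - {segment: shank_r, position: [40.0, -10.0, -50.0]}
  adductor_magnus:
    points:
      - {segment: pelvis, position: [30.0, 0.0, -80.0]}
      - {segment: thigh_r, position: [-30.0, 0.0, -300.0]}
  gracilis:
    points:
      - {segment: pelvis, position: [25.0, 10.0, -85.0]}
      - {segment: shank_r, position: [-25.0, 10.0, -80.0]}
  gluteus_medius:
    points:
      - {segment: pelvis, position: [110.0, -10.0, 0.0]}
      - {segment: thigh_r, position: [40.0, -5.0, -30.0]}
  semimembranosus:
    points:
      - {segment: pelvis, position: [45.0, -45.0, -80.0]}
      - {segment: shank_r, position: [-25.0, -15.0, -70.0]}
  pectoralis_major:
    points:
      - {segment: upper_trunk, position: [60.0, 80.0, 180.0]}
      - {segment: upper_arm_r, position: [10.0, 20.0, -60.0]}
  latissimus_dorsi:
    points:
      - {segment: pelvis, position: [20.0, -90.0, 100.0]}
      - {segment: upper_arm_r, position: [-10.0, 5.0, -70.0]}
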