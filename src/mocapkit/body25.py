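"""The BODY_25 keypoint layout used by the pose estimator.

Index map (0-24): 0 nose, 1 neck, 2 r-shoulder, 3 r-elbow, 4 r-wrist,
5 l-shoulder, 6 l-elbow, 7 l-wrist, 8 mid-hip, 9 r-hip, 10 r-knee,
11 r-ankle, 12 l-hip, 13 l-knee, 14 l-ankle, 15 r-eye, 16 l-eye,
17 r-ear, 18 l-ear, 19 l-big-toe, 20 l-small-toe, 21 l-heel,
22 r-big-toe, 23 r-small-toe, 24 r-heel.
"""

N_KEYPOINTS = 25

KEYPOINT_NAMES = (
    "nose",
    "neck",
    "r_shoulder",
    "r_elbow",
    "r_wrist",
    "l_shoulder",
    "l_elbow",
    "l_wrist",
    "mid_hip",
    "r_hip",
    "r_knee",
    "r_ankle",
    "l_hip",
    "l_knee",
    "l_ankle",
    "r_eye",
    "l_eye",
    "r_ear",
    "l_ear",
    "l_big_toe",
    "l_small_toe",
    "l_heel",
    "r_big_toe",
    "r_small_toe",
    "r_heel",
)

NAME_TO_INDEX = {name: i for i, name in enumerate(KEYPOINT_NAMES)}

#: Homologous (left, right) keypoint index pairs, the candidates for
#: left-right label interchange: shoulders, elbows, wrists, hips, knees,
#: ankles, big toes, small toes, heels.
LEFT_RIGHT_PAIRS = (
    (5, 2),
    (6, 3),
    (7, 4),
    (12, 9),
    (13, 10),
    (14, 11),
    (19, 22),
    (20, 23),
    (21, 24),
)

#: Default mapping from the six evaluated joints (right side) to
#: BODY_25 keypoint indices.
RIGHT_JOINT_KEYPOINTS = {
    "shoulder": 2,
    "elbow": 3,
    "wrist": 4,
    "hip": 9,
    "knee": 10,
    "ankle": 11,
}

LEFT_JOINT_KEYPOINTS = {
    "shoulder": 5,
    "elbow": 6,
    "wrist": 7,
    "hip": 12,
    "knee": 13,
    "ankle": 14,
}
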