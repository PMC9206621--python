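"""Relational knee kinematics from femur and tibia poses.

Registered poses of the two bones are reduced to the six clinical
joint-coordinate-system parameters (floating-axis convention): three
rotations (flexion-extension, abduction-adduction, internal-external) and
three translations (medial-lateral, anterior-posterior,
distraction-compression), all zero at the CT-capture reference.
"""

from hybridreg import (
    AnatomicalAxes,
    BoneAxes,
    RigidPose,
    error_statistics,
    jcs_decompose,
    relative_pose,
)

axes = AnatomicalAxes(
    femur=BoneAxes.canonical(origin=(0.0, -20.0, 0.0)),
    tibia=BoneAxes.canonical(origin=(0.0, 15.0, 0.0)),
)

# femur fixed; tibia drawn 3 mm toward the source (the anatomical
# anterior direction, -z) with no rotation: a pure anterior drawer
femur = RigidPose()
tibia = RigidPose(tz=-3.0)
drawer = jcs_decompose(relative_pose(femur, tibia), axes)
print("pure 3 mm anterior drawer:")
for name in drawer.names():
    print(f"{name:>24s}: {getattr(drawer, name):8.3f}")

# tibia rotated 15 deg about the scan x axis (parallel to the femoral
# medial-lateral axis but through the CT origin): flexion plus the
# lever-arm translation of the tibial origin, reported in the joint basis
flexed = jcs_decompose(relative_pose(femur, RigidPose(rx=15.0)), axes)
print("\n15 deg rotation about the scan ML axis:")
for name in flexed.names():
    print(f"{name:>24s}: {getattr(flexed, name):8.3f}")

# error table against a slightly perturbed estimate of the flexed pose
est = jcs_decompose(relative_pose(femur, RigidPose(rx=15.2)), axes)
print()
print(error_statistics([est], [flexed]))
# Rotating about an axis offset from the joint produces both
# flexion_extension and translations - the decomposition separates them.
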