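"""Simulate a fluoroscopy frame with a known ground-truth pose.

The frame is the DRR pushed through a monotone nonlinear intensity remap
(inversion + gamma), additive Gaussian noise and optional pincushion
distortion — the appearance differences that make CT-to-fluoroscopy
registration a multimodal problem.
"""

from hybridreg import RigidPose, default_camera, generate_phantom, simulate_fluoroscopy
from hybridreg.phantom import FluoroSimSpec, PhantomSpec

volume = generate_phantom(PhantomSpec())
camera = default_camera()
truth = RigidPose(tz=-20.0, rx=-5.0, ry=5.0)

sim = FluoroSimSpec(noise_sigma=0.02, distortion_k1=0.05, rng_seed=11)
frame = simulate_fluoroscopy(volume, truth, camera, sim)

print(f"frame shape: {frame.shape}")
print(f"background level: {frame.pixels[0, 0]:.3f} (bright: the remap inverts)")
print(f"darkest bone pixel: {frame.pixels.min():.3f}")
print(f"intensity range: [{frame.pixels.min():.3f}, {frame.pixels.max():.3f}]")
# Bone is dark on a bright background — the opposite polarity of the DRR —
# so similarity measures that assume a linear intensity relationship fail.
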