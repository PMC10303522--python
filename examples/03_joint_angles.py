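"""Recover hip/knee angles from sensor quaternions with unknown mountings.

The generator applies a random fixed mounting rotation to each sensor and
prepends a two-second neutral stance; the kinematics module identifies
the mountings from that static interval and recovers the angle series.
"""

import numpy as np

from emgkin import joint_angles
from emgkin.synthetic import GaitProfile, gen_angles, gen_pose_streams

angles = gen_angles(GaitProfile(n_cycles=4, fs=200.0), seed=1)
poses, mountings, calib = gen_pose_streams(angles, seed=2)

series = joint_angles(poses["waist"], poses["thigh"], poses["shank"],
                      calib_interval=calib)
gait = series.timestamps >= calib[1]

hip_rms = np.sqrt(np.mean((series.hip_deg[gait] - angles.hip_deg) ** 2))
knee_rms = np.sqrt(np.mean((series.knee_deg[gait] - angles.knee_deg) ** 2))
print(f"thigh mounting quaternion (unknown to the estimator): "
      f"{np.round(mountings['thigh'], 3)}")
print(f"hip  recovery RMS error: {hip_rms:.2e} deg")
print(f"knee recovery RMS error: {knee_rms:.2e} deg")
print(f"hip range:  {series.hip_deg.min():7.2f} .. {series.hip_deg.max():6.2f} deg")
print(f"knee range: {series.knee_deg.min():7.2f} .. {series.knee_deg.max():6.2f} deg")
# With noise-free quaternions the recovery is exact to numerical
# precision, independent of the mounting rotations.
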