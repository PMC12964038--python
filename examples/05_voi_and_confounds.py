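"""VOI extraction from a 4D image and confound regression.

The atlas ships the six central-autonomic-network spheres (MNI mm).
Here a synthetic 4D image carries a known signal inside the amygdala
sphere; extraction recovers it, and the 128-s high-pass plus motion
confound regression removes slow drift while staying orthogonal to the
confounds.
"""

import nibabel as nib
import numpy as np

from canheart import CAN_ATLAS, RoiTimeseries, extract_voi, nuisance_regress

amy = next(v for v in CAN_ATLAS if v.label == "AMY")
print(f"AMY sphere: center {amy.center} mm, radius {amy.radius} mm")

# synthetic 1 mm-voxel image centred on the amygdala sphere
rng = np.random.default_rng(0)
shape = (20, 20, 20, 120)
affine = np.eye(4)
affine[:3, 3] = np.asarray(amy.center) - 10.0
img = rng.normal(0, 0.1, shape)
signal = np.sin(np.linspace(0, 8 * np.pi, shape[3]))
ii, jj, kk = np.meshgrid(*[np.arange(s) for s in shape[:3]], indexing="ij")
world = np.stack([ii, jj, kk], -1) + (np.asarray(amy.center) - 10.0)
inside = np.sum((world - amy.center) ** 2, -1) <= amy.radius**2
img[inside] += signal
ts = extract_voi(nib.Nifti1Image(img, affine), spec=amy)
print(
    "in-sphere voxels carry a sinusoid; eigenvariate correlation with it: "
    f"{np.corrcoef(ts, signal)[0, 1]:.3f}"
)

# confound regression on a longer run: slow drift + motion projected out
n, tr = 400, 0.961
t = np.arange(n) * tr
series = np.sin(2 * np.pi * 0.05 * t) + 0.5 * np.sin(2 * np.pi * 0.002 * t)
roi = RoiTimeseries(series[:, None], ("AMY",), tr)
motion = rng.normal(0, 0.01, (n, 6))
clean = nuisance_regress(roi, motion)
kept = np.std(clean.data[:, 0]) / np.std(np.sin(2 * np.pi * 0.05 * t))
print(f"0.05 Hz signal preserved after 128-s high-pass: {100 * kept:.0f}% of its sd")
print(f"residual-confound max inner product: {np.max(np.abs(clean.data.T @ motion)):.2e}")
print("-> the eigenvariate tracks the shared signal; the slow 0.002 Hz drift")
print("   is removed while the in-band signal and orthogonality are kept.")
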