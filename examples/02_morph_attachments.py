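"""Transfer atlas attachment points onto a subject by landmark registration.

Muscle origin/insertion points are invisible on MRI, so they live on a
generic atlas.  A 12-DOF affine fitted to named bony-landmark pairs maps
them onto each subject; points that land off the bone can be snapped to the
nearest point of a bone surface mesh.
"""

import numpy as np

from segrepeat import PhantomSpec, apply_transform, fit_affine, make_phantom, snap_to_surface

study = make_phantom(PhantomSpec(seed=7))

fit = fit_affine(study.atlas_landmarks, study.landmarks)
print(f"affine fit over {len(study.landmarks)} landmarks, "
      f"RMS residual {fit.rms_residual_mm:.2e} mm")
err = np.abs(fit.matrix - study.true_affine.matrix).max()
print(f"max |fitted - true| matrix entry: {err:.2e}  (exact recovery, no jitter)")

morphed = apply_transform(fit, study.atlas_attachments)
print("morphed origin   :", np.round(morphed["origin"], 3))
print("morphed insertion:", np.round(morphed["insertion"], 3))

point = morphed["origin"] + np.array([3.0, 0.0, 0.0])  # slightly off the bone
snapped, moved = snap_to_surface(point, study.bone_surface, max_snap_mm=60.0)
print(f"snap moved the point {np.linalg.norm(snapped - point):.2f} mm "
      f"onto the bone surface (snapped={moved})")
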