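"""Correlate a light-microscopy field with an EM stack.

Fit the 2D affine mapping LM coordinates onto EM coordinates from
landmark pairs, and match optical sections (240 nm steps) to the EM
sections (60 nm steps) they span.
"""

import numpy as np

from chromovol.registration import (
    LandmarkSet,
    collapse_sections,
    fit_affine,
    match_sections,
)

rng = np.random.default_rng(0)
lm = rng.uniform(0, 40, (6, 2))
A = np.array([[1.08, 0.04], [-0.03, 1.02]])   # slight scale + shear
em = lm @ A.T + np.array([5.0, -2.0]) + rng.normal(0, 0.1, lm.shape)

tf = fit_affine(LandmarkSet(lm_xy=lm, em_xy=em, em_step_nm=60.0))
print("fitted matrix:\n", tf.matrix.round(4))
print("fitted offset:", tf.offset.round(3))
print(f"rms residual: {tf.rms_residual_um:.3f} um")

for k in range(3):
    ems = list(match_sections(240.0, 60.0, k))
    print(f"optical section {k} spans EM sections {ems}")

stack = rng.random((8, 4, 4))
collapsed = collapse_sections(stack, 4, mode="mean")
print(f"collapsed {stack.shape[0]} EM sections -> {collapsed.shape[0]} optical-scale sections")
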