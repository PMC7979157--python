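"""Benchmark the sub-pixel rigid registration estimator.

Translates a rendered vessel-channel frame by 50 known random sub-pixel
shifts (uniform in [-5, 5] px per axis) and reports the error of the
upsampled cross-correlation estimate. The pipeline relies on this stage to
remove animal motion to better than 0.2 px.
"""

import numpy as np

from pvsflow.validation import registration_shift_errors

errors = registration_shift_errors(n_shifts=50, seed=1)
print(f"shifts tested : 50, uniform in [-5, 5] px per axis")
print(f"max |error|   : {errors.max():.4f} px")
print(f"median |error|: {np.median(errors):.4f} px")
# Errors well below 0.2 px mean frame-to-frame animal motion is removed to
# a small fraction of a pixel, so it does not leak into particle velocities
# (0.2 px/frame at 30 Hz and 1.29 um/px would alias to ~7.7 um/s).
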