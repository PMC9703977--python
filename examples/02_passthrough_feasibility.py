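"""Pass-through feasibility: how much stimulus information do RF pixels carry?

Instead of brain responses, the stimulus's own pixel values at the RF-center
locations are transported back into pixel space. With one voxel per pixel
the RFS image equals the grayscale stimulus exactly; with a subsampled
retinotopy, coverage (and thus the information available to the generator)
drops accordingly.
"""

import numpy as np

from voxel2pixel import Canvas
from voxel2pixel.synthetic_data import (
    make_retinotopy, make_toy_video, passthrough_rfs, luminance,
)

canvas = Canvas(32, 32)
video = make_toy_video(8, canvas, seed=1)

full = make_retinotopy(canvas.n_pixels, canvas, jitter_sds=(0, 0, 0), seed=1)
rfs = passthrough_rfs(video, full)
err = np.abs(rfs[:, 0] - luminance(video)).max()
print(f"one voxel per pixel: max |RFS - grayscale stimulus| = {err:.2e}")

sparse = make_retinotopy(canvas.n_pixels // 4, canvas, seed=1)
rfs_sparse = passthrough_rfs(video, sparse)
for roi, cov in sparse.coverage.items():
    print(f"{roi}: coverage {cov:.1%}")
r = np.corrcoef(rfs_sparse[:, 0].ravel(), luminance(video).ravel())[0, 1]
print(f"quarter-density retinotopy still correlates r = {r:.3f} with the stimulus")
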