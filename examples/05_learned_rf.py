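"""The learnable receptive-field input layer.

The fixed transport is the delta-mask/M operator; the learnable variant
multiplies each voxel's masked weight by a trainable scalar initialized to
1, so before training the two coincide exactly, and gradient descent can
then re-weight unreliable voxels.
"""

import numpy as np

from voxel2pixel import Canvas, RFCenterTable
from voxel2pixel.autodiff import Adam, Tensor
from voxel2pixel.networks import LearnableRFLayer
from voxel2pixel.rf_transport import (
    apply_transport, build_point_transport, make_perturbation_mask,
)

rng = np.random.default_rng(0)
canvas = Canvas(16, 16)
table = RFCenterTable("V1", rng.uniform(0, 16, 80), rng.uniform(0, 16, 80))
mask = make_perturbation_mask(table, canvas)
op = build_point_transport(table, canvas)

layer = LearnableRFLayer(mask)
resp = rng.normal(size=(4, 1, 80))
init_diff = max(np.abs(layer(resp).data[n, 0] - apply_transport(op, resp[n, 0])).max()
                for n in range(4))
print(f"at initialization |learned - fixed| = {init_diff:.2e}")

# make voxel 0 unreliable: its response is pure noise w.r.t. the target
target = Tensor(layer(resp).data.copy())
resp_noisy = resp.copy()
resp_noisy[:, :, 0] += 5 * rng.normal(size=(4, 1))
opt = Adam(layer.parameters(), lr=0.05)
for step in range(60):
    opt.zero_grad()
    loss = (layer(resp_noisy) - target).abs().mean()
    loss.backward()
    opt.step()
print(f"after training, weight of the corrupted voxel: {layer.v.data[0]:+.3f} "
      f"(median |weight| elsewhere: {np.median(np.abs(layer.v.data[1:])):.3f})")
# the layer learns to down-weight the voxel whose response stopped carrying
# information about its receptive-field location.
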