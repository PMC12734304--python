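"""Tour of the computational primitives with hand-checkable numbers.

Shows the depthwise-separable factorisation, the fusion gate's softmax
weighting, the parameter-free attention on a degenerate input, and the
dilated kernel's enlarged receptive field."""

import numpy as np

from voxslim import ILSAttention, LMFBlock, pooled_descriptor
from voxslim.engine import Conv3d, softmax

# depthwise-separable conv: ones kernel over a ones 3x3x3 patch sums to 27
dw = Conv3d(1, 1, 3, padding=0, rng=np.random.default_rng(0))
dw.weight.data[...] = 1.0
pw = Conv3d(1, 1, 1, padding=0, rng=np.random.default_rng(0))
pw.weight.data[...] = 1.0
x = np.ones((1, 1, 3, 3, 3), dtype=np.float32)
print("depthwise+pointwise on a ones cube:", float(pw.forward(dw.forward(x))[0, 0, 0, 0, 0]))

# fusion gate: softmax turns branch scores into convex weights
alpha = softmax(np.array([2.0, 1.0, 0.1]))
print("gate scores [2.0, 1.0, 0.1] ->", np.round(alpha, 2), "(sum", alpha.sum(), ")")

# pooled descriptor of two concatenated 4x3x3 maps has one entry per channel
rng = np.random.default_rng(1)
maps = [rng.normal(size=(1, 1, 4, 3, 3)).astype(np.float32) for _ in range(2)]
print("pooled descriptor length:", pooled_descriptor(maps).shape[1])

# ILS attention on a constant channel: zero variance pins the mask at sigmoid(0.5)
const = np.full((1, 1, 2, 2, 2), 3.0, dtype=np.float32)
y = ILSAttention().forward(const)
print(f"ILS on constant input scales by {float(y[0,0,0,0,0] / 3.0):.5f} "
      f"(= sigmoid(0.5) = {1/(1+np.exp(-0.5)):.5f})")

# dilation: a 3^3 kernel at rate 2 sees a 5^3 neighbourhood on a sparse lattice
dil = Conv3d(1, 1, 3, padding=0, dilation=2, rng=np.random.default_rng(2))
dil.weight.data[...] = 1.0
hot = np.zeros((1, 1, 5, 5, 5), dtype=np.float32)
hot[0, 0, 4, 4, 4] = 1.0   # corner of the 5^3 patch: on the dilated lattice
print("dilated kernel reaches the 5^3 corner:", float(dil.forward(hot).squeeze()) != 0.0)
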