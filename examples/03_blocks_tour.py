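"""A tour of the three building blocks and their contracts.

MixConv gates are independent sigmoids; SK fusion weights are a softmax pair
summing to one; the DFEU combines its two branch estimates through the
feature-space scattering-model inversion.
"""

import numpy as np

from dunet import nn
from dunet.blocks import (
    DFEU,
    DFEUParams,
    MixConvBlock,
    MixConvParams,
    SKFusion,
    dfeu_reconstruct,
)

rng = np.random.default_rng(0)
x = nn.Tensor(rng.standard_normal((1, 8, 16, 16)).astype(np.float32))

block = MixConvBlock(MixConvParams(8), np.random.default_rng(1)).eval()
w1, w2 = block.gates(x)
print(f"MixConv gate ranges: w1 [{w1.data.min():.3f}, {w1.data.max():.3f}], "
      f"w1+w2 mean {float((w1.data + w2.data).mean()):.3f}")
# sigmoid gates: each in (0,1), their sum is NOT constrained to 1

fuse = SKFusion(8, np.random.default_rng(2)).eval()
s1, s2 = fuse.weights(x, x * 0.5)
print(f"SK weight sum per channel: {float((s1.data + s2.data).mean()):.6f}")
# softmax over the two branches: sums to exactly 1

unit = DFEU(DFEUParams(8), np.random.default_rng(3)).eval()
a = unit.estimate_atmospheric(x)
t = unit.estimate_transmission(x)
print(f"DFEU branch ranges: A ({a.data.min():.3f}, {a.data.max():.3f}), "
      f"t ({t.data.min():.3f}, {t.data.max():.3f})")
# both sigmoid-bounded in (0,1), spatially varying

# the reconstruction is the exact inverse of feature-space hazing
j = nn.Tensor(rng.standard_normal((1, 8, 16, 16)))
tt = nn.Tensor(rng.uniform(0.2, 1.0, (1, 8, 16, 16)))
aa = nn.Tensor(rng.uniform(0.0, 1.0, (1, 8, 16, 16)))
hazed = j * tt + aa * (1.0 - tt)
err = np.abs(dfeu_reconstruct(hazed, aa, tt, 0.0).data - j.data).max()
print(f"feature-space inversion max error: {err:.2e}")
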