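"""Inspect the extractor's building blocks on small feature maps.

Shows the depthwise-separable cost advantage (the ratio tends to
1/N + 1/Dk^2, hence 1/9 for 3x3 kernels and many output channels), the
channel-shuffle permutation, and the efficient-channel-attention weights.
"""

import numpy as np

from histotune.nn.ops import (
    ConvCostSpec,
    channel_shuffle,
    eca_module,
    separable_conv_cost,
    shuffle_permutation,
)

for n in (8, 64, 1024):
    q1, q2, ratio = separable_conv_cost(ConvCostSpec(df=16, dk=3, m=8, n=n))
    print(f"N={n:5d}: separable {q1:>9d} MACs vs standard {q2:>10d} -> ratio {ratio:.4f}")
print("limit for 3x3 kernels: 1/9 =", f"{1/9:.4f}")

print("\nchannel shuffle, C=8 in g=2 groups:", shuffle_permutation(8, 2))

rng = np.random.default_rng(0)
x = rng.random((4, 6, 6))
out, attn = eca_module(x, rng.standard_normal(3) * 0.5)
print("\nECA attention weights per channel:", np.round(attn, 3))
print("(each in (0,1); channel c of the output is the input scaled by its weight)")
shuffled = channel_shuffle(x, 2)
print("shuffle preserves content: channel multisets equal ->",
      np.allclose(np.sort(x.sum(axis=(1, 2))), np.sort(shuffled.sum(axis=(1, 2)))))
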