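"""Build the full-size hybrid ResNeXt-SE + Transformer classifier and trace
the tensor shapes through it.

A [2, 151, 1000] time-frequency input (real/imag channels, 0-15 Hz at 0.1 Hz
resolution, 10 s at 100 Hz) is reduced 32x spatially by the convolutional
extractor, flattened into a 160-token sequence for the Transformer encoder,
mean-pooled and classified.
"""

import numpy as np

from stecg import ModelConfig, build_model

model = build_model(ModelConfig(), seed=0).eval()
print(f"parameters: {model.n_parameters():,}")

x = np.random.default_rng(0).standard_normal((1, 2, 151, 1000)).astype("f4")
for name, shape in model.trace_shapes(x).items():
    print(f"  {name:12s} {shape}")
print("logits are unnormalised scores over the 5 AAMI classes (N,S,V,F,Q)")
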