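"""Print the full 13-convolution network layer table.

Every row shows a layer's output shape and trainable parameter count;
the totals line gives the 45,846,329 parameters of the binary model.
"""

from afibnet import ModelConfig, format_trace

print(format_trace(ModelConfig.afibnet(n_classes=2)))
print("\nInput 2700 samples -> 78 nodes per feature map after 5 poolings; "
      "the 78x512 flatten feeds two 1000-unit dense layers and a sigmoid head.")
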