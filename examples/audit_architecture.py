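"""Audit the default CNN's learnable-parameter counts.

Builds the declarative network description (three conv/batchnorm/
activation/maxpool blocks and a 4-way fully connected head), computes
each layer's learnable count from the layer arithmetic, and compares
with the published per-layer values; also instantiates the model and
confirms the introspected parameter total agrees.
"""

from actsign import (ActivationSpec, audit_table2, build_network,
                     default_network, forward_shapes)

net = default_network()
report = audit_table2(net)
print(report.format_text())

print("\nper-layer output shapes (H, W, C):")
for layer, shape in zip(net.layers, forward_shapes(net)):
    print(f"  {layer.name:<14}{shape}")

model = build_network(net, ActivationSpec("rectified_softsign"), seed=0)
print("\nmodel parameter total:", model.parameter_count(),
      "== audit total:", report.total_computed)
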