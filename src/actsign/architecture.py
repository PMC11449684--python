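"""Declarative CNN architecture: builder, shape inference, parameter audit.

The default network is a compact 16-layer stack for four-class brain-MRI
classification: input 224×224×3, then three conv→batchnorm→activation→
maxpool blocks (32, 64 and 32 filters of size 3×3, conv stride 3 with
padding 1; 3×3 max pools of stride 1 with padding 1), then a fully
connected layer to the class scores, softmax and the classification
output.  Under the standard output-size rule

    out = floor((in + 2p − k) / s) + 1

the spatial chain is 224 → 75 → 75 → 25 → 25 → 9 → 9, so the flattened
feature width entering the fully connected layer is 9·9·32 = 2592 and
the published per-layer learnable counts (896, 64, 18496, 128, 18464,
64, 10372) all fall out of the arithmetic; :func:`audit_table2` checks
them explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import _nn
from .activations import ActivationSpec

__all__ = [
    "LayerSpec",
    "NetworkSpec",
    "AuditReport",
    "default_network",
    "count_learnables",
    "forward_shapes",
    "build_network",
    "audit_table2",
    "TABLE2_PRINTED_COUNTS",
    "TABLE2_PRINTED_FLAT_DIM",
]

LAYER_KINDS = ("input", "conv", "batchnorm", "activation", "maxpool",
               "fully_connected", "softmax", "classification")


class ArchitectureError(ValueError):
    """Invalid layer/network specification."""


@dataclass(frozen=True)
class LayerSpec:
    """One layer of the declarative network description.

    ``filters``/``kernel``/``stride``/``padding`` apply to conv and
    maxpool layers; ``out_units`` to the fully connected layer;
    ``in_channels`` (conv) and ``in_features`` (fully connected) are
    filled in by shape inference when left at 0.
    """

    kind: str
    name: str = ""
    filters: int = 0
    kernel: tuple[int, int] = (0, 0)
    stride: tuple[int, int] = (1, 1)
    padding: int = 0
    in_channels: int = 0
    in_features: int = 0
    out_units: int = 0

    def __post_init__(self):
        if self.kind not in LAYER_KINDS:
            raise ArchitectureError(f"unknown layer kind {self.kind!r}")
        if self.kind == "conv":
            if self.filters <= 0:
                raise ArchitectureError(f"conv layer {self.name!r}: filters must be > 0")
            if min(self.kernel) < 1 or min(self.stride) < 1:
                raise ArchitectureError(f"conv layer {self.name!r}: kernel and stride must be >= 1")
        if self.kind == "maxpool" and (min(self.kernel) < 1 or min(self.stride) < 1):
            raise ArchitectureError(f"maxpool layer {self.name!r}: kernel and stride must be >= 1")


@dataclass(frozen=True)
class NetworkSpec:
    """Ordered layer list plus input geometry and class count."""

    layers: tuple[LayerSpec, ...]
    input_shape: tuple[int, int, int] = (224, 224, 3)
    num_classes: int = 4


def default_network(input_shape: tuple[int, int, int] = (224, 224, 3),
                    num_classes: int = 4) -> NetworkSpec:
    """The default three-block network (filters 32/64/32)."""
    def block(i, filters):
        return [
            LayerSpec("conv", f"conv_{i}", filters=filters, kernel=(3, 3),
                      stride=(3, 3), padding=1),
            LayerSpec("batchnorm", f"batchnorm_{i}"),
            LayerSpec("activation", f"activation_{i}"),
            LayerSpec("maxpool", f"maxpool_{i}", kernel=(3, 3), stride=(1, 1),
                      padding=1),
        ]
    layers = [LayerSpec("input", "imageinput")]
    for i, f in enumerate([32, 64, 32], start=1):
        layers += block(i, f)
    layers += [
        LayerSpec("fully_connected", "fc", out_units=num_classes),
        LayerSpec("softmax", "softmax"),
        LayerSpec("classification", "classoutput"),
    ]
    return NetworkSpec(tuple(layers), input_shape=input_shape, num_classes=num_classes)


def count_learnables(layer: LayerSpec) -> int:
    """Learnable-parameter count of a single (fully specified) layer.

    conv: (k_h·k_w·C_in + 1)·filters; batchnorm: 2·C (scale + offset;
    running statistics are state, not learnables); fully connected:
    out·in + out; all other kinds carry no learnables.
    """
    if layer.kind == "conv":
        if layer.in_channels <= 0:
            raise ArchitectureError(f"conv layer {layer.name!r}: in_channels unknown")
        kh, kw = layer.kernel
        return (kh * kw * layer.in_channels + 1) * layer.filters
    if layer.kind == "batchnorm":
        if layer.in_channels <= 0:
            raise ArchitectureError(f"batchnorm layer {layer.name!r}: channels unknown")
        return 2 * layer.in_channels
    if layer.kind == "fully_connected":
        if layer.in_features <= 0:
            raise ArchitectureError(f"fc layer {layer.name!r}: in_features unknown")
        return layer.out_units * layer.in_features + layer.out_units
    if layer.kind in ("input", "activation", "maxpool", "softmax", "classification"):
        return 0
    raise ArchitectureError(f"unknown layer kind {layer.kind!r}")


def _resolve(net: NetworkSpec) -> tuple[list[LayerSpec], list[tuple[int, int, int]]]:
    """Chain channel counts / feature widths through the stack.

    Returns the layers with ``in_channels``/``in_features`` filled in,
    and the per-layer output shapes (H, W, C); shapes after the
    fully connected layer are recorded as (1, 1, units).
    """
    h, w, c = net.input_shape
    resolved, shapes = [], []
    flat = None
    for layer in net.layers:
        if layer.kind == "input":
            pass
        elif layer.kind == "conv":
            kh, kw = layer.kernel
            sh, sw = layer.stride
            p = layer.padding
            if h + 2 * p < kh or w + 2 * p < kw:
                raise ArchitectureError(
                    f"layer {layer.name!r}: kernel {layer.kernel} exceeds input "
                    f"({h}x{w} with padding {p})")
            layer = replace(layer, in_channels=c)
            h = (h + 2 * p - kh) // sh + 1
            w = (w + 2 * p - kw) // sw + 1
            c = layer.filters
        elif layer.kind == "batchnorm":
            layer = replace(layer, in_channels=c)
        elif layer.kind == "maxpool":
            kh, kw = layer.kernel
            sh, sw = layer.stride
            p = layer.padding
            if h + 2 * p < kh or w + 2 * p < kw:
                raise ArchitectureError(
                    f"layer {layer.name!r}: kernel {layer.kernel} exceeds input "
                    f"({h}x{w} with padding {p})")
            h = (h + 2 * p - kh) // sh + 1
            w = (w + 2 * p - kw) // sw + 1
        elif layer.kind == "fully_connected":
            flat = h * w * c
            layer = replace(layer, in_features=flat)
            h, w, c = 1, 1, layer.out_units
        if h <= 0 or w <= 0:
            raise ArchitectureError(f"layer {layer.name!r}: non-positive output size {h}x{w}")
        resolved.append(layer)
        shapes.append((h, w, c))
    return resolved, shapes


def forward_shapes(net: NetworkSpec) -> list[tuple[int, int, int]]:
    """Per-layer output shapes (H, W, C) under floor((in+2p−k)/s)+1."""
    return _resolve(net)[1]


def flattened_dim(net: NetworkSpec) -> int:
    """Feature width entering the fully connected layer."""
    resolved, _ = _resolve(net)
    for layer in resolved:
        if layer.kind == "fully_connected":
            return layer.in_features
    raise ArchitectureError("network has no fully_connected layer")


def build_network(net: NetworkSpec, act: ActivationSpec, seed: int) -> _nn.Model:
    """Instantiate a trainable model from the spec.

    Weight initialization is He fan-in normal for conv and fully
    connected layers, batchnorm scale 1 / offset 0, all drawn from a
    ``numpy`` PCG64 generator seeded with ``seed`` — two builds with the
    same seed have bit-identical initial parameters.  The model's
    ``forward`` returns pre-softmax class scores; softmax is applied by
    ``predict`` / ``predict_proba``.
    """
    resolved, _ = _resolve(net)
    rng = np.random.Generator(np.random.PCG64(seed))
    layers: list[_nn.Layer] = []
    for layer in resolved:
        if layer.kind == "conv":
            layers.append(_nn.Conv2D(layer.in_channels, layer.filters,
                                     layer.kernel, layer.stride, layer.padding, rng))
        elif layer.kind == "batchnorm":
            layers.append(_nn.BatchNorm2D(layer.in_channels))
        elif layer.kind == "activation":
            layers.append(_nn.Activation(act))
        elif layer.kind == "maxpool":
            layers.append(_nn.MaxPool2D(layer.kernel, layer.stride, layer.padding))
        elif layer.kind == "fully_connected":
            layers.append(_nn.Flatten())
            layers.append(_nn.Dense(layer.in_features, layer.out_units, rng))
        # input/softmax/classification carry no computation here
    return _nn.Model(layers, net.input_shape, net.num_classes)


def total_learnables(net: NetworkSpec) -> int:
    resolved, _ = _resolve(net)
    return sum(count_learnables(layer) for layer in resolved)


#: Published per-layer learnable counts of the reference configuration.
TABLE2_PRINTED_COUNTS = {
    "conv_1": 896,
    "batchnorm_1": 64,
    "conv_2": 18496,
    "batchnorm_2": 128,
    "conv_3": 18464,
    "batchnorm_3": 64,
    "fc": 10372,
}

#: Published flattened feature width entering the fully connected layer.
TABLE2_PRINTED_FLAT_DIM = 2592


@dataclass
class AuditReport:
    """Computed-vs-printed learnable counts for the reference network."""

    rows: list[dict] = field(default_factory=list)
    computed_flat_dim: int = 0
    printed_flat_dim: int = TABLE2_PRINTED_FLAT_DIM
    flat_dim_match: bool = False

    @property
    def total_computed(self) -> int:
        return sum(r["computed"] for r in self.rows)

    @property
    def all_match(self) -> bool:
        printed_rows = [r for r in self.rows if r["printed"] is not None]
        return all(r["match"] for r in printed_rows) and self.flat_dim_match

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame(self.rows)

    def format_text(self) -> str:
        lines = [f"{'layer':<14}{'kind':<16}{'computed':>10}{'printed':>10}  match"]
        for r in self.rows:
            printed = "" if r["printed"] is None else str(r["printed"])
            match = "" if r["printed"] is None else ("yes" if r["match"] else "NO")
            lines.append(f"{r['name']:<14}{r['kind']:<16}{r['computed']:>10}{printed:>10}  {match}")
        lines.append(f"total computed learnables: {self.total_computed}")
        lines.append(f"flattened width: computed {self.computed_flat_dim}, "
                     f"printed {self.printed_flat_dim} "
                     f"({'match' if self.flat_dim_match else 'MISMATCH'})")
        return "\n".join(lines)


def audit_table2(net: NetworkSpec | None = None) -> AuditReport:
    """Audit a network's learnable counts against the published table.

    Every layer appears in the report; rows whose name carries a
    published count are flagged match/mismatch.  The published table
    labels its third batchnorm "1*1*64" although the preceding conv has
    32 filters; the printed count 64 = 2·32 is what is audited.
    """
    if net is None:
        net = default_network()
    resolved, _ = _resolve(net)
    report = AuditReport()
    for layer in resolved:
        computed = count_learnables(layer)
        printed = TABLE2_PRINTED_COUNTS.get(layer.name)
        report.rows.append({
            "name": layer.name,
            "kind": layer.kind,
            "computed": computed,
            "printed": printed,
            "match": (printed == computed) if printed is not None else None,
        })
    report.computed_flat_dim = flattened_dim(net)
    report.flat_dim_match = report.computed_flat_dim == report.printed_flat_dim
    return report
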