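"""The single-trial P300 CNN and its exact layer-by-layer accounting.

The network consumes one (fused) epoch as a single-plane image of shape
``(time, channels, 1)`` and maps it to two class probabilities
(target / non-target):

====  ==============================  ==========================
L1    Conv2D 16 filters, 64-weight kernel, same, ReLU
L2    Dropout (0.5)
L3    Conv2D 32 filters, 6x6 kernel, same, ReLU
L4    MaxPooling 2x2, stride 2, valid
L5    Flatten
L6    Dense 64, ReLU
L7    Dense 8, ReLU
L8    Dense 2, softmax
====  ==============================  ==========================

The first kernel's published parameter count (1,040 = 16 x (64 + 1)) pins
only its *element count* at 64; the default geometry is 8x8 and any other
64-element kernel (e.g. 64x1, 16x4, 32x2) is selectable and reproduces the
same count.  The second kernel is forced to 6x6 by
18,464 = 32 x (6*6*16 + 1).

Every layer's trainable-parameter count is available in closed form
(:func:`count_parameters`) and is asserted against the realized weight
arrays whenever a concrete network is supplied.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from . import nn
from .errors import ConfigurationError, IntegrityError

__all__ = ["LayerSpec", "ModelSpec", "build_cnn", "count_parameters",
           "closed_form_count"]

#: Kernel geometries whose element count matches the published first layer.
FIRST_KERNEL_CHOICES = {(8, 8), (64, 1), (1, 64), (16, 4), (4, 16), (32, 2), (2, 32)}


@dataclass(frozen=True)
class LayerSpec:
    """One layer of the architecture with its realized output shape."""

    name: str
    kind: str                      # conv | dropout | maxpool | flatten | dense
    output_shape: tuple
    n_params: int
    activation: str | None = None
    kernel_shape: tuple | None = None
    n_units_or_filters: int | None = None
    padding: str | None = None
    dropout_rate: float | None = None


@dataclass(frozen=True)
class ModelSpec:
    """Layer-by-layer description of a concrete network build."""

    input_time: int
    input_channels: int
    layers: tuple
    n_classes: int = 2

    @property
    def total_params(self) -> int:
        return sum(l.n_params for l in self.layers)

    def to_json(self, indent: int = 2) -> str:
        """Architecture summary (name, type, output shape, parameter count)."""
        return json.dumps({
            "input_shape": [self.input_time, self.input_channels, 1],
            "n_classes": self.n_classes,
            "total_params": self.total_params,
            "layers": [asdict(l) for l in self.layers],
        }, indent=indent)


def closed_form_count(kind: str, *, filters=0, kernel=(0, 0), in_maps=0,
                      in_dim=0, units=0) -> int:
    """Closed-form trainable-parameter count for one layer.

    conv: ``filters * (kh * kw * in_maps + 1)``; dense: ``(in + 1) * units``;
    everything else: 0.
    """
    if kind == "conv":
        return filters * (kernel[0] * kernel[1] * in_maps + 1)
    if kind == "dense":
        return (in_dim + 1) * units
    return 0


def build_cnn(input_time: int, input_channels: int,
              first_kernel: tuple = (8, 8), dropout_rate: float = 0.5,
              seed: int = 0) -> tuple[nn.Network, ModelSpec]:
    """Construct the classifier for any fused input shape.

    Parameters
    ----------
    input_time, input_channels
        Epoch geometry, e.g. (351, 16) for two-person parallel fusion or
        (702, 8) for two-person serial fusion.
    first_kernel
        Geometry of the first convolution; must contain 64 weight elements.
    seed
        Seeds the Glorot-uniform weight initialization.

    Returns
    -------
    (network, spec)
        The trainable network and its :class:`ModelSpec`, whose per-layer
        counts are verified against the realized weights before returning.
    """
    kh, kw = first_kernel
    if kh * kw != 64:
        raise ConfigurationError(
            f"first kernel {first_kernel} has {kh * kw} elements; the "
            f"architecture requires 64 (choose one of {sorted(FIRST_KERNEL_CHOICES)})")
    if input_time < 2 or input_channels < 2:
        raise ConfigurationError(
            f"input {input_time}x{input_channels} too small for 2x2 pooling")
    if not 0.0 <= dropout_rate < 1.0:
        raise ConfigurationError("dropout_rate must be in [0, 1)")

    rng = np.random.default_rng(seed)
    t, c = input_time, input_channels
    pt, pc = t // 2, c // 2
    flat = pt * pc * 32

    network = nn.Network([
        nn.Conv2D(1, 16, (kh, kw), activation="relu", rng=rng),
        nn.Dropout(dropout_rate),
        nn.Conv2D(16, 32, (6, 6), activation="relu", rng=rng),
        nn.MaxPool2D((2, 2)),
        nn.Flatten(),
        nn.Dense(flat, 64, activation="relu", rng=rng),
        nn.Dense(64, 8, activation="relu", rng=rng),
        nn.Dense(8, 2, activation="softmax", rng=rng),
    ])

    spec = ModelSpec(input_time=t, input_channels=c, layers=(
        LayerSpec("L1", "conv", (t, c, 16),
                  closed_form_count("conv", filters=16, kernel=(kh, kw), in_maps=1),
                  activation="relu", kernel_shape=(kh, kw),
                  n_units_or_filters=16, padding="same"),
        LayerSpec("L2", "dropout", (t, c, 16), 0, dropout_rate=dropout_rate),
        LayerSpec("L3", "conv", (t, c, 32),
                  closed_form_count("conv", filters=32, kernel=(6, 6), in_maps=16),
                  activation="relu", kernel_shape=(6, 6),
                  n_units_or_filters=32, padding="same"),
        LayerSpec("L4", "maxpool", (pt, pc, 32), 0, kernel_shape=(2, 2),
                  padding="valid"),
        LayerSpec("L5", "flatten", (flat,), 0),
        LayerSpec("L6", "dense", (64,),
                  closed_form_count("dense", in_dim=flat, units=64),
                  activation="relu", n_units_or_filters=64),
        LayerSpec("L7", "dense", (8,),
                  closed_form_count("dense", in_dim=64, units=8),
                  activation="relu", n_units_or_filters=8),
        LayerSpec("L8", "dense", (2,),
                  closed_form_count("dense", in_dim=8, units=2),
                  activation="softmax", n_units_or_filters=2),
    ))
    count_parameters(spec, network)  # integrity check: realized == closed form
    return network, spec


def count_parameters(spec: ModelSpec,
                     network: nn.Network | None = None) -> list[int]:
    """Per-layer trainable-parameter counts.

    With a concrete ``network``, assert that the framework-realized counts
    (actual weight-array sizes) equal the closed form, raising
    :class:`IntegrityError` naming the first offending layer.
    """
    counts = [l.n_params for l in spec.layers]
    if network is not None:
        if len(network.layers) != len(spec.layers):
            raise IntegrityError("network and spec have different depths")
        for lspec, layer in zip(spec.layers, network.layers):
            realized = layer.n_params
            if realized != lspec.n_params:
                raise IntegrityError(
                    f"layer {lspec.name}: realized {realized} parameters, "
                    f"closed form {lspec.n_params}")
    return counts
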