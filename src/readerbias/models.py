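"""Classifier backbone registry.

Two backbone names are recognized. ``small_cnn`` is the desk-scale network
implemented in :mod:`readerbias._nn` (three conv blocks, global pooling, a
linear two-class head) and is what all built-in experiments use. ``resnet18``
names the full-scale configuration for real chest-X-ray work; this build does
not ship a ResNet implementation and raises a clear error if it is requested.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._nn import SmallCNN
from .exceptions import ConfigurationError, UnsupportedBackboneError

BACKBONES = ("small_cnn", "resnet18")


@dataclass(frozen=True)
class ModelSpec:
    backbone: str = "small_cnn"
    input_side_px: int = 32
    weight_init_seed: int = 0
    n_classes: int = 2

    def __post_init__(self) -> None:
        if self.backbone not in BACKBONES:
            raise ConfigurationError(
                f"backbone must be one of {BACKBONES}, got {self.backbone!r}"
            )
        if self.n_classes != 2:
            raise ConfigurationError("this pipeline is binary: n_classes must be 2")
        if self.input_side_px < 8 or self.input_side_px % 8:
            raise ConfigurationError(
                f"input_side_px must be a positive multiple of 8, "
                f"got {self.input_side_px}"
            )


def build_model(spec: ModelSpec) -> SmallCNN:
    """Instantiate a freshly initialized backbone from its spec."""
    if spec.backbone == "resnet18":
        raise UnsupportedBackboneError(
            "the resnet18 backbone requires a GPU deep-learning stack and is "
            "not included in this build; use backbone='small_cnn'"
        )
    return SmallCNN(
        in_channels=3,
        n_classes=spec.n_classes,
        seed=spec.weight_init_seed,
        input_side=spec.input_side_px,
    )
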