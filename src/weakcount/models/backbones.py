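"""Convolutional feature extractors behind a common interface.

Two families:

* ``tiny_cnn`` — four conv/batch-norm/ReLU blocks with 2× pooling after
  the first three (output stride 8, 64 channels). This is the default,
  sized so the full counting pipelines train in seconds on a CPU.
* ``paper_resnet50`` / ``paper_resnet101`` — bottleneck residual
  networks with the standard stage layouts (3-4-6-3 and 3-4-23-3),
  output stride 32, 2048 channels, for users who want the full-scale
  architecture the counting methods were originally built on. They are
  far too slow for CPU training at realistic tile sizes and exist for
  structural parity, transfer or GPU-port scenarios.

``build_backbone`` returns ``(module, out_channels, output_stride)``.
"""

from __future__ import annotations

import numpy as np

from ..nn.layers import (
    BatchNorm2d,
    Conv2d,
    Layer,
    MaxPool2d,
    Param,
    ReLU,
    Sequential,
)

__all__ = ["build_backbone", "BACKBONES"]


class Bottleneck(Layer):
    """1×1 → 3×3 → 1×1 residual bottleneck with projection shortcut."""

    def __init__(self, cin: int, cmid: int, cout: int, stride: int, rng) -> None:
        self.body = Sequential(
            Conv2d(cin, cmid, 1, rng),
            BatchNorm2d(cmid),
            ReLU(),
            Conv2d(cmid, cmid, 3, rng, stride=stride, padding=1),
            BatchNorm2d(cmid),
            ReLU(),
            Conv2d(cmid, cout, 1, rng),
            BatchNorm2d(cout),
        )
        self.proj: Sequential | None = None
        if stride != 1 or cin != cout:
            self.proj = Sequential(
                Conv2d(cin, cout, 1, rng, stride=stride), BatchNorm2d(cout)
            )
        self.relu = ReLU()

    def params(self) -> list[Param]:
        out = self.body.params()
        if self.proj is not None:
            out += self.proj.params()
        return out

    def state(self):
        out = {f"body.{k}": v for k, v in self.body.state().items()}
        if self.proj is not None:
            out.update({f"proj.{k}": v for k, v in self.proj.state().items()})
        return out

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        main = self.body.forward(x, train=train)
        skip = x if self.proj is None else self.proj.forward(x, train=train)
        return self.relu.forward(main + skip, train=train)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy = self.relu.backward(dy)
        dx = self.body.backward(dy)
        if self.proj is None:
            dx = dx + dy
        else:
            dx = dx + self.proj.backward(dy)
        return dx


def _tiny_cnn(rng: np.random.Generator) -> tuple[Sequential, int, int]:
    net = Sequential(
        Conv2d(3, 16, 3, rng, padding=1),
        BatchNorm2d(16),
        ReLU(),
        MaxPool2d(2),
        Conv2d(16, 32, 3, rng, padding=1),
        BatchNorm2d(32),
        ReLU(),
        MaxPool2d(2),
        Conv2d(32, 64, 3, rng, padding=1),
        BatchNorm2d(64),
        ReLU(),
        MaxPool2d(2),
        Conv2d(64, 64, 3, rng, padding=1),
        BatchNorm2d(64),
        ReLU(),
    )
    return net, 64, 8


def _resnet(rng: np.random.Generator, depths: tuple[int, ...]) -> tuple[Sequential, int, int]:
    layers: list[Layer] = [
        Conv2d(3, 64, 7, rng, stride=2, padding=3),
        BatchNorm2d(64),
        ReLU(),
        MaxPool2d(2),
    ]
    cin = 64
    for stage, n_blocks in enumerate(depths):
        cmid = 64 * 2**stage
        cout = cmid * 4
        for b in range(n_blocks):
            stride = 2 if (stage > 0 and b == 0) else 1
            layers.append(Bottleneck(cin, cmid, cout, stride, rng))
            cin = cout
    return Sequential(*layers), cin, 32


BACKBONES = {
    "tiny_cnn": _tiny_cnn,
    "paper_resnet50": lambda rng: _resnet(rng, (3, 4, 6, 3)),
    "paper_resnet101": lambda rng: _resnet(rng, (3, 4, 23, 3)),
}


def build_backbone(name: str, rng: np.random.Generator) -> tuple[Sequential, int, int]:
    try:
        factory = BACKBONES[name]
    except KeyError:
        raise ValueError(
            f"unknown backbone {name!r}; available: {sorted(BACKBONES)}"
        ) from None
    return factory(rng)
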