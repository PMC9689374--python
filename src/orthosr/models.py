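"""The four super-resolution architectures, modified for 1:1 output.

All four networks map a one-channel H×W image to a one-channel H×W
image: because the fused LR volume already lives on the thin-slice
grid, no spatial upsampling is needed, so the bicubic pre-interpolation
of SRCNN/VDSR and the pixel-shuffle upsampling blocks of
SRResNet/EDSR are replaced by the identity.

Structural constants:

* SRCNN — three convolution stages (9-5-5 kernels, 64→32 filters),
  plain feed-forward.
* VDSR — 20 convolution layers of 3×3/64 filters predicting the
  residual (global input-to-output skip); trained with gradient
  clipping.
* SRResNet — 16 residual blocks (conv-BN-PReLU-conv-BN) with a long
  feature skip, plus the global 1:1 skip.
* EDSR — 32 residual blocks (conv-ReLU-conv, no normalization layers)
  with residual scaling 0.1, a long feature skip, plus the global 1:1
  skip.

The residual-predicting networks initialise their final convolution
with down-scaled weights so the network starts close to the identity
map; zeroing that layer exactly makes each of them the identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import (
    BatchNorm2d,
    Conv2d,
    Module,
    PReLU,
    ReLU,
    ResidualBlock,
    Sequential,
    SkipConnection,
)

__all__ = ["ArchitectureSpec", "Network", "build_model", "ARCHITECTURES"]

ARCHITECTURES = ("SRCNN", "VDSR", "SRResNet", "EDSR")

_FINAL_LAYER_SCALE = 0.1  # near-identity start for residual networks


@dataclass
class ArchitectureSpec:
    """Name plus the structural constants of one architecture.

    ``width`` is the base filter count (64 as in the original
    architectures); it is configurable so desk-scale experiments can
    use narrow networks without changing any structure.
    """

    name: str
    width: int = 64
    n_blocks: int = field(init=False)
    residual_scaling: float | None = field(init=False)
    batch_norm: bool = field(init=False)

    def __post_init__(self) -> None:
        if self.name not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.name!r}")
        self.n_blocks = {"SRCNN": 0, "VDSR": 0, "SRResNet": 16, "EDSR": 32}[self.name]
        self.residual_scaling = 0.1 if self.name == "EDSR" else None
        self.batch_norm = self.name == "SRResNet"


class Network(Module):
    """A named architecture instance with audit helpers."""

    def __init__(self, spec: ArchitectureSpec, root: Module) -> None:
        self.spec = spec
        self.root = root

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return self.root.forward(x, training=training)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return self.root.backward(grad)

    def params(self):
        return self.root.params()

    def modules(self):
        yield self
        yield from self.root.modules()

    # -- structural audit -------------------------------------------------
    def count_residual_blocks(self) -> int:
        return sum(isinstance(m, ResidualBlock) for m in self.root.modules())

    def count_conv_layers(self) -> int:
        return sum(isinstance(m, Conv2d) for m in self.root.modules())

    def has_norm_layers(self) -> bool:
        return any(isinstance(m, BatchNorm2d) for m in self.root.modules())

    def final_conv(self) -> Conv2d:
        convs = [m for m in self.root.modules() if isinstance(m, Conv2d)]
        return convs[-1]

    def get_state(self) -> list[np.ndarray]:
        state = [p.value.copy() for p in self.params()]
        state += [
            arr.copy()
            for m in self.root.modules()
            if isinstance(m, BatchNorm2d)
            for arr in (m.running_mean, m.running_var)
        ]
        return state

    def set_state(self, state: list[np.ndarray]) -> None:
        params = self.params()
        for p, v in zip(params, state[: len(params)]):
            p.value[...] = v
        bn_state = state[len(params) :]
        i = 0
        for m in self.root.modules():
            if isinstance(m, BatchNorm2d):
                m.running_mean[...] = bn_state[i]
                m.running_var[...] = bn_state[i + 1]
                i += 2


def _srcnn(width: int, rng: np.random.Generator) -> Module:
    w2 = max(width // 2, 1)
    return Sequential(
        Conv2d(1, width, 9, rng),
        ReLU(),
        Conv2d(width, w2, 5, rng),
        ReLU(),
        Conv2d(w2, 1, 5, rng),
    )


def _vdsr(width: int, rng: np.random.Generator) -> Module:
    layers: list[Module] = [Conv2d(1, width, 3, rng), ReLU()]
    for _ in range(18):
        layers += [Conv2d(width, width, 3, rng), ReLU()]
    layers.append(Conv2d(width, 1, 3, rng, weight_scale=_FINAL_LAYER_SCALE))
    return SkipConnection(Sequential(*layers))


def _srresnet(width: int, rng: np.random.Generator) -> Module:
    head = Sequential(Conv2d(1, width, 9, rng), PReLU(width))
    blocks: list[Module] = [
        ResidualBlock(
            Sequential(
                Conv2d(width, width, 3, rng),
                BatchNorm2d(width),
                PReLU(width),
                Conv2d(width, width, 3, rng),
                BatchNorm2d(width),
            )
        )
        for _ in range(16)
    ]
    post = Sequential(Conv2d(width, width, 3, rng), BatchNorm2d(width))
    trunk = SkipConnection(Sequential(*blocks, post))
    tail = Conv2d(width, 1, 9, rng, weight_scale=_FINAL_LAYER_SCALE)
    return SkipConnection(Sequential(head, trunk, tail))


def _edsr(width: int, rng: np.random.Generator) -> Module:
    head = Conv2d(1, width, 3, rng)
    blocks: list[Module] = [
        ResidualBlock(
            Sequential(
                Conv2d(width, width, 3, rng),
                ReLU(),
                Conv2d(width, width, 3, rng),
            ),
            scale=0.1,
        )
        for _ in range(32)
    ]
    post = Conv2d(width, width, 3, rng)
    trunk = SkipConnection(Sequential(*blocks, post))
    tail = Conv2d(width, 1, 3, rng, weight_scale=_FINAL_LAYER_SCALE)
    return SkipConnection(Sequential(head, trunk, tail))


_BUILDERS = {"SRCNN": _srcnn, "VDSR": _vdsr, "SRResNet": _srresnet, "EDSR": _edsr}


def build_model(
    spec: ArchitectureSpec | str, rng: np.random.Generator | int | None = None
) -> Network:
    """Instantiate an untrained network for ``spec``.

    ``rng`` seeds the weight initialisation (an int is accepted for
    convenience). The forward pass of every architecture preserves the
    spatial shape of its input.
    """
    if isinstance(spec, str):
        spec = ArchitectureSpec(spec)
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return Network(spec, _BUILDERS[spec.name](spec.width, rng))
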