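"""Generator and discriminator architectures for the 3D CycleGAN.

The generator is a shallow volumetric encoder–decoder: six 3×3×3
convolutions with ReLU (the fifth strided, halving each spatial dimension),
two transposed convolutions restoring the original size (the first stride 2,
the second stride 1 as a refinement stage), and a 1×1×1 convolution with a
tanh head — so the output always matches the input shape and lies in (−1, 1).
Shallow-but-3D is the point: full volumes avoid the slice-wise banding
artifacts of 2D translation models while staying trainable at modest memory.

The discriminator is a 4-stage strided patch classifier trained with a
least-squares (MSE-to-label) objective.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .layers import Conv3d, ConvTranspose3d, LeakyReLU, ReLU, Sequential, Tanh


@dataclass
class GanConfig:
    input_shape: tuple = (32, 32, 32)
    base_kernels: int = 16
    #: encoder channel multipliers per conv stage
    channel_mult: tuple = (1, 2, 4, 8, 8, 8)
    lambda_cycle: float = 10.0
    learning_rate: float = 2e-4
    epochs: int = 30
    batch_size: int = 1
    seed: int = 0
    device: str = "cpu"

    def __post_init__(self):
        self.input_shape = tuple(int(n) for n in self.input_shape)
        if any(n % 2 for n in self.input_shape):
            raise ValueError("input_shape must be divisible by 2 "
                             "(one downsampling stage)")
        if self.base_kernels < 4:
            raise ValueError("base_kernels must be >= 4")
        if self.device != "cpu":
            raise ValueError("only cpu execution is supported")


def generator_channels(config):
    k = config.base_kernels
    enc = [k * m for m in config.channel_mult]
    dec = [enc[-1] // 2, enc[-1] // 4]
    return enc, dec


def build_generator(config, seed=None):
    """Encoder–decoder generator per :class:`GanConfig`; deterministic in the
    seed."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    enc, dec = generator_channels(config)
    layers = []
    c_prev = 1
    for stage, c in enumerate(enc):
        stride = 2 if stage == 4 else 1  # downsample ×2 after the 4th stage
        layers += [Conv3d(c_prev, c, kernel=3, stride=stride, pad=1, rng=rng),
                   ReLU()]
        c_prev = c
    layers += [ConvTranspose3d(c_prev, dec[0], kernel=4, stride=2, pad=1, rng=rng),
               ReLU(),
               ConvTranspose3d(dec[0], dec[1], kernel=3, stride=1, pad=1, rng=rng),
               ReLU(),
               Conv3d(dec[1], 1, kernel=1, stride=1, pad=0, rng=rng),
               Tanh()]
    return Sequential(layers)


def build_discriminator(config, seed=None):
    """Strided 3D patch classifier: 4 conv stages then a 1×1×1 score map."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    k = config.base_kernels
    chans = [k, 2 * k, 4 * k, 8 * k]
    layers = []
    c_prev = 1
    for c in chans:
        layers += [Conv3d(c_prev, c, kernel=3, stride=2, pad=1, rng=rng),
                   LeakyReLU(0.2)]
        c_prev = c
    layers += [Conv3d(c_prev, 1, kernel=1, stride=1, pad=0, rng=rng)]
    return Sequential(layers)


def parameter_count(net):
    return int(sum(p.value.size for p in net.params()))


def toy_gan_config(seed=0, epochs=30, input_shape=(32, 32, 32)):
    """The supported CPU test-scale configuration: 32³ volumes, minimum
    channel widths. Full-resolution training is a GPU-profile exercise."""
    return GanConfig(input_shape=input_shape, base_kernels=4,
                     channel_mult=(1, 2, 2, 4, 4, 4), epochs=epochs, seed=seed)
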