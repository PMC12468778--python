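"""DnCNN image projectors for unrolled reconstruction.

The projector PC stands in for projection onto the (unknown) set of
plausible images.  Architecture: an input convolution (1 -> width channels,
same padding) with ReLU, L intermediate convolutions (width -> width) each
followed by batch normalization and ReLU, and a single-channel output
convolution.  Same padding makes the network resolution-agnostic, so one
configuration serves any image side length >= the kernel size.

The projection step comes in two flavors: direct, x_{i+1} = PC(x~_i), and
residual, x_{i+1} = x~_i + PC(x~_i), selected per experiment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigurationError
from .nn import BatchNorm2d, Conv2d, ReLU

__all__ = ["ProjectorConfig", "DnCNN", "build_dncnn", "project"]


@dataclass(frozen=True)
class ProjectorConfig:
    """Hyperparameters of a DnCNN projector.

    L counts intermediate conv+BN+ReLU blocks (the depth knob ablated over
    {3, 5, 10, 15}); it is distinct from the skip factor of the skip-layer
    loss.  ``batchnorm`` toggles BN in the intermediate blocks; the first
    and last layers never carry BN (common DnCNN convention).  ``final_bias``
    keeps a bias on the reconstruction layer (default on).  With
    ``final_zero_init`` the reconstruction layer starts as the zero map, so
    at initialization a residual projection step is the identity and the
    whole unrolled network reproduces the plain iterative algorithm encoded
    by its coefficients; training then departs from a known-sound scheme.
    """

    L: int = 3
    width: int = 64
    kernel: int = 3
    residual: bool = True
    batchnorm: bool = True
    final_bias: bool = True
    final_zero_init: bool = True

    def __post_init__(self):
        if self.L < 0:
            raise ConfigurationError(f"L must be >= 0, got {self.L}")
        if self.width < 1:
            raise ConfigurationError(f"width must be >= 1, got {self.width}")
        if self.kernel < 1 or self.kernel % 2 == 0:
            raise ConfigurationError(f"kernel must be odd and >= 1, got {self.kernel}")


class DnCNN:
    """A seeded DnCNN instance mapping (N, side, side) -> (N, side, side)."""

    def __init__(self, config: ProjectorConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        c, k = config.width, config.kernel
        self.layers: list = [Conv2d(1, c, k, rng=rng), ReLU()]
        for _ in range(config.L):
            self.layers.append(Conv2d(c, c, k, rng=rng))
            if config.batchnorm:
                self.layers.append(BatchNorm2d(c))
            self.layers.append(ReLU())
        final = Conv2d(c, 1, k, bias=config.final_bias, rng=rng)
        if config.final_zero_init:
            # start as the zero map so a residual projection step is the
            # identity and the unrolled network at init realizes the plain
            # iterative algorithm its coefficients encode
            final.W.value[...] = 0.0
        self.layers.append(final)

    @property
    def params(self):
        return [p for layer in self.layers for p in layer.params]

    @property
    def n_params(self) -> int:
        return sum(layer.n_params for layer in self.layers)

    @property
    def buffers(self) -> list[np.ndarray]:
        """Non-trainable state (BatchNorm running statistics), in order."""
        out = []
        for layer in self.layers:
            if isinstance(layer, BatchNorm2d):
                out.extend([layer.running_mean, layer.running_var])
        return out

    def set_buffers(self, arrays: list[np.ndarray]):
        it = iter(arrays)
        for layer in self.layers:
            if isinstance(layer, BatchNorm2d):
                layer.running_mean = np.asarray(next(it), dtype=np.float64).copy()
                layer.running_var = np.asarray(next(it), dtype=np.float64).copy()

    def forward(self, x: np.ndarray, train: bool = False):
        """Run the network; returns (output, tape) with x of shape (N, H, W)."""
        h = x[:, None, :, :]
        tape = []
        for layer in self.layers:
            if isinstance(layer, BatchNorm2d):
                h, cache = layer.forward(h, train=train)
            else:
                h, cache = layer.forward(h)
            tape.append(cache)
        return h[:, 0, :, :], tape

    def backward(self, dout: np.ndarray, tape) -> np.ndarray:
        """Reverse sweep; accumulates parameter grads, returns d(input)."""
        dh = dout[:, None, :, :]
        for layer, cache in zip(reversed(self.layers), reversed(tape)):
            dh = layer.backward(dh, cache)
        return dh[:, 0, :, :]

    def __call__(self, x: np.ndarray) -> np.ndarray:
        single = x.ndim == 2
        out, _ = self.forward(x[None] if single else x, train=False)
        return out[0] if single else out

    def get_weights(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params]

    def set_weights(self, weights: list[np.ndarray]):
        for p, w in zip(self.params, weights):
            p.value[...] = w


def build_dncnn(config: ProjectorConfig, seed: int = 0) -> DnCNN:
    """Construct a seeded DnCNN projector from its configuration."""
    return DnCNN(config, seed=seed)


def project(projector, x_tilde: np.ndarray, residual: bool) -> np.ndarray:
    """One projection step: PC(x~) directly, or x~ + PC(x~) with a residual
    connection."""
    out = projector(x_tilde)
    return x_tilde + out if residual else out
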