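"""Training losses over reconstruction traces.

Three families, all built from per-step squared errors e_i = ||x_i - x*||^2
(pixel-sum per image, averaged over a batch):

* last-layer:            l_ll   = e_T
* weighted intermediate: l_i,w  = sum_{i=1..T} w^(T-i) e_i,  w in (0, 1]
* skip-L:                l_s,L  = sum over steps {T, T-L, ..., L},
                                  L a divisor of T

w = 1 supervises every step equally; as w -> 0 the weighted loss collapses
onto the last-layer loss, and the skip factor interpolates the same two
endpoints (L=1 gives l_i,1, L=T gives l_ll).  These limits hold exactly and
are asserted in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigurationError, ShapeError

__all__ = [
    "LossSpec",
    "step_weights",
    "per_step_sq_errors",
    "last_layer_loss",
    "weighted_intermediate_loss",
    "skip_layer_loss",
    "evaluate_loss",
    "PAPER_OMEGA_GRID",
]

FAMILIES = ("last_layer", "weighted_intermediate", "skip_L")

# the omega ablation grid shipped as a preset (plus skip factor 5)
PAPER_OMEGA_GRID = (1.0, 0.95, 0.85, 0.75, 0.5, 0.25, 0.1, 0.01)


@dataclass(frozen=True)
class LossSpec:
    """Loss-family selector with its parameters."""

    family: str = "weighted_intermediate"
    omega: float = 1.0
    skip: int = 1

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ConfigurationError(
                f"family must be one of {FAMILIES}, got {self.family!r}"
            )
        if self.family == "weighted_intermediate" and not 0 < self.omega <= 1:
            raise ConfigurationError(f"omega must lie in (0, 1], got {self.omega}")
        if self.family == "skip_L" and self.skip < 1:
            raise ConfigurationError(f"skip factor must be >= 1, got {self.skip}")

    def weights(self, T: int) -> np.ndarray:
        return step_weights(self, T)


def step_weights(spec: LossSpec, T: int) -> np.ndarray:
    """Per-step weights w_i (i = 1..T) so the loss is sum_i w_i ||x_i - x*||^2."""
    if T < 1:
        raise ConfigurationError(f"T must be >= 1, got {T}")
    w = np.zeros(T)
    if spec.family == "last_layer":
        w[-1] = 1.0
    elif spec.family == "weighted_intermediate":
        w[:] = spec.omega ** (T - np.arange(1, T + 1))
    else:
        if T % spec.skip != 0:
            raise ConfigurationError(
                f"skip factor {spec.skip} must divide T={T}"
            )
        w[spec.skip - 1::spec.skip] = 1.0
    return w


def per_step_sq_errors(trace, x_star: np.ndarray) -> np.ndarray:
    """e_i = ||x_i - x*||^2 per step, pixel-sum then batch mean."""
    xs = trace.xs if hasattr(trace, "xs") else list(trace)
    x_star = np.asarray(x_star, dtype=np.float64)
    errs = np.empty(len(xs))
    for i, x in enumerate(xs):
        x = np.asarray(x, dtype=np.float64)
        if x.shape != x_star.shape:
            raise ShapeError("trace element", x_star.shape, x.shape)
        d = (x - x_star) ** 2
        if d.ndim == 2:
            errs[i] = d.sum()
        else:  # batch: mean over images of the pixel-sum
            errs[i] = d.reshape(d.shape[0], -1).sum(axis=1).mean()
    return errs


def last_layer_loss(trace, x_star: np.ndarray) -> float:
    """l_ll = ||x_T - x*||^2."""
    return float(per_step_sq_errors(trace, x_star)[-1])


def weighted_intermediate_loss(trace, x_star: np.ndarray, omega: float) -> float:
    """l_i,w = sum_i w^(T-i) ||x_i - x*||^2 with w in (0, 1]."""
    spec = LossSpec(family="weighted_intermediate", omega=omega)
    errs = per_step_sq_errors(trace, x_star)
    return float(np.dot(step_weights(spec, len(errs)), errs))


def skip_layer_loss(trace, x_star: np.ndarray, skip: int) -> float:
    """l_s,L summing errors at steps {L, 2L, ..., T}; L must divide T."""
    spec = LossSpec(family="skip_L", skip=skip)
    errs = per_step_sq_errors(trace, x_star)
    return float(np.dot(step_weights(spec, len(errs)), errs))


def evaluate_loss(spec: LossSpec, trace, x_star: np.ndarray) -> float:
    """Evaluate any configured loss family on a trace."""
    errs = per_step_sq_errors(trace, x_star)
    return float(np.dot(step_weights(spec, len(errs)), errs))
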