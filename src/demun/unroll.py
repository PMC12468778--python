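"""Iteration engines for unrolled reconstruction.

Given measurements y = A x* + w, every scheme alternates a data-consistency
step producing a pre-projection estimate x~_i with a projection step
x_{i+1} = PC(x~_i) (or x~_i + PC(x~_i) with a residual connection):

* **PGD** — projected gradient descent, x~_i = x_i + mu * A^T(y - A x_i).
* **Nesterov** — the accelerated first-order method: the gradient step is
  taken at the extrapolated point z_i = x_i + gamma_i (x_i - x_{i-1}) with
  the canonical schedule gamma_i = (t_{i-1} - 1) / t_i, t_0 = 1,
  t_i = (1 + sqrt(1 + 4 t_{i-1}^2)) / 2.
* **AMP** — approximate message passing with an Onsager-corrected residual,
  z_t = y - A x_t + (1/m) z_{t-1} * div(eta_{t-1}); the divergence of the
  denoiser/projector is estimated by a seeded Monte-Carlo probe (exact
  closed forms exist for linear denoisers and are tested against it).
* **DeMUN** — the deep-memory update
  x~_i = alpha_i x_i + sum_{j<=i} beta_{j,i} A^T(y - A x_j), a trainable
  linear combination of the current iterate and *all* stored gradients.
  With alpha_i = 1, beta_{i,i} = mu and beta_{j,i} = 0 for j < i it reduces
  to PGD exactly; suitable coefficient choices likewise reproduce Nesterov
  iterates, so DeMUN strictly generalizes those schemes and training picks
  the algorithm from data.

`UnrolledNetwork` is the trainable end-to-end object (per-step DnCNN
projectors plus memory coefficients) with an explicit reverse sweep;
`run_unrolled` executes any scheme with arbitrary projector callables and
returns the full `ReconstructionTrace`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import measurement as meas
from .exceptions import ConfigurationError
from .nn import Param
from .projector import DnCNN, ProjectorConfig

__all__ = [
    "MemoryCoefficients",
    "IterateState",
    "ReconstructionTrace",
    "nesterov_gammas",
    "pgd_step",
    "demun_step",
    "nesterov_step",
    "amp_step",
    "soft_threshold",
    "mc_divergence",
    "amp_recover",
    "run_unrolled",
    "UnrolledNetwork",
]

SCHEMES = ("pgd", "nesterov", "amp", "demun")


# ---------------------------------------------------------------------------
# coefficient and state containers
# ---------------------------------------------------------------------------

@dataclass
class MemoryCoefficients:
    """Per-step scalars of the deep-memory update.

    ``alphas[i]`` weights the current iterate x_i; ``betas[i][j]`` weights
    the stored gradient g_j = A^T(y - A x_j) for j <= i.  Storage is
    triangular: step i holds exactly i+1 beta entries, T(T+1)/2 in total.
    """

    alphas: np.ndarray
    betas: list

    def __post_init__(self):
        self.alphas = np.asarray(self.alphas, dtype=np.float64)
        self.betas = [np.asarray(b, dtype=np.float64) for b in self.betas]
        T = len(self.alphas)
        if len(self.betas) != T:
            raise ConfigurationError(
                f"need one beta row per step: {len(self.betas)} rows for T={T}"
            )
        for i, b in enumerate(self.betas):
            if b.shape != (i + 1,):
                raise ConfigurationError(
                    f"beta row {i} must have {i + 1} entries, got shape {b.shape}"
                )

    @property
    def T(self) -> int:
        return len(self.alphas)

    @property
    def n_beta(self) -> int:
        return sum(b.size for b in self.betas)

    @classmethod
    def pgd_view(cls, T: int, mu: float) -> "MemoryCoefficients":
        """The fixed view recovering plain PGD with step size mu."""
        betas = []
        for i in range(T):
            b = np.zeros(i + 1)
            b[i] = mu
            betas.append(b)
        return cls(alphas=np.ones(T), betas=betas)


@dataclass
class IterateState:
    """Mutable state threaded through the per-step functions."""

    y: np.ndarray
    x: np.ndarray
    i: int = 0
    T: int = 1
    grads: list = field(default_factory=list)  # g_0 .. g_i images
    x_prev: np.ndarray | None = None           # for Nesterov momentum
    amp_z: np.ndarray | None = None            # previous AMP residual
    amp_div: float = 0.0                       # divergence from previous step


@dataclass
class ReconstructionTrace:
    """Ordered post-projection estimates x_1..x_T (and optionally x~_i)."""

    xs: list
    x_tildes: list | None = None

    def __len__(self) -> int:
        return len(self.xs)

    @property
    def final(self) -> np.ndarray:
        return self.xs[-1]

    def as_array(self) -> np.ndarray:
        return np.stack(self.xs)


# ---------------------------------------------------------------------------
# per-step updates
# ---------------------------------------------------------------------------

def nesterov_gammas(T: int) -> np.ndarray:
    """Canonical momentum schedule gamma_i = (t_{i-1} - 1)/t_i, t_0 = 1."""
    t = 1.0
    gammas = np.zeros(T)
    for i in range(T):
        t_next = (1.0 + np.sqrt(1.0 + 4.0 * t * t)) / 2.0
        gammas[i] = (t - 1.0) / t_next
        t = t_next
    return gammas


def _gradient(model: meas.MeasurementModel, y: np.ndarray, x: np.ndarray) -> np.ndarray:
    return meas.adjoint(model, y - meas.forward(model, x))


def pgd_step(state: IterateState, model: meas.MeasurementModel, mu: float) -> np.ndarray:
    """x~_i = x_i + mu * A^T(y - A x_i)."""
    return state.x + mu * _gradient(model, state.y, state.x)


def demun_step(state: IterateState, coeffs: MemoryCoefficients,
               via: str = "conv1x1") -> np.ndarray:
    """x~_i = alpha_i x_i + sum_{j<=i} beta_{j,i} g_j.

    ``via="conv1x1"`` evaluates the update as a one-by-one convolution over
    the (i+2)-channel stack [x_i, g_0, ..., g_i]; ``via="sum"`` accumulates
    the weighted sum term by term.  Both paths agree to float rounding.
    """
    i = state.i
    if len(state.grads) != i + 1:
        raise ConfigurationError(
            f"gradient history incomplete: have {len(state.grads)}, step i={i} "
            f"needs {i + 1}"
        )
    a = coeffs.alphas[i]
    b = coeffs.betas[i]
    if via == "sum":
        out = a * state.x
        for j in range(i + 1):
            out = out + b[j] * state.grads[j]
        return out
    if via == "conv1x1":
        stack = np.stack([state.x] + list(state.grads), axis=-3)
        w = np.concatenate([[a], b])
        return np.einsum("c,...cij->...ij", w, stack)
    raise ConfigurationError(f"unknown demun evaluation path {via!r}")


def nesterov_step(state: IterateState, model: meas.MeasurementModel, mu: float,
                  gamma: float) -> np.ndarray:
    """Gradient step at the extrapolated point z = x_i + gamma (x_i - x_{i-1})."""
    x_prev = state.x_prev if state.x_prev is not None else np.zeros_like(state.x)
    z = state.x + gamma * (state.x - x_prev)
    return z + mu * _gradient(model, state.y, z)


def soft_threshold(v: np.ndarray, tau: float) -> np.ndarray:
    """Elementwise soft-thresholding, the proximal map of the l1 norm."""
    return np.sign(v) * np.maximum(np.abs(v) - tau, 0.0)


def mc_divergence(denoiser, v: np.ndarray, seed: int = 0, eps: float = 1e-4,
                  probes: int = 1) -> float:
    """Monte-Carlo estimate of div eta(v) = E_b[ b^T (eta(v+eps b)-eta(v)) / eps ]."""
    rng = np.random.default_rng(seed)
    base = denoiser(v)
    total = 0.0
    for _ in range(probes):
        b = rng.standard_normal(v.shape)
        total += float(np.sum(b * (denoiser(v + eps * b) - base))) / eps
    return total / probes


def amp_step(state: IterateState, model: meas.MeasurementModel,
             denoiser=None, onsager: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """One AMP data step: returns (x~, z) with the Onsager-corrected residual.

    z_t = y - A x_t + (1/m) z_{t-1} * div(eta_{t-1}); x~ = x_t + A^T z_t.
    With the Onsager term forced off (or at t=0) this is a plain gradient
    step with mu = 1.  Intended for Gaussian sensing matrices.
    """
    import warnings
    if model.kind != "gaussian":
        warnings.warn("AMP assumes a Gaussian sensing matrix", stacklevel=2)
    z = state.y - meas.forward(model, state.x)
    if onsager and state.amp_z is not None:
        z = z + state.amp_z * (state.amp_div / model.m)
    return state.x + meas.adjoint(model, z), z


def amp_recover(model: meas.MeasurementModel, y: np.ndarray, denoiser,
                iters: int = 30, seed: int = 0,
                denoiser_divergence=None) -> np.ndarray:
    """Run denoising-AMP to convergence on a single measurement vector.

    ``denoiser(v, sigma_hat)`` maps a pseudo-data image and the estimated
    effective noise level to a denoised image.  ``denoiser_divergence`` may
    supply an analytic divergence; otherwise a seeded single-probe
    Monte-Carlo estimate is used.
    """
    state = IterateState(y=y, x=np.zeros((model.side, model.side)), T=iters)
    for t in range(iters):
        state.i = t
        v, z = amp_step(state, model)
        sigma_hat = float(np.linalg.norm(z) / np.sqrt(model.m))
        eta = lambda u: denoiser(u, sigma_hat)  # noqa: E731
        x_next = eta(v)
        if denoiser_divergence is not None:
            div = denoiser_divergence(v, sigma_hat)
        else:
            div = mc_divergence(eta, v, seed=seed * 1000 + t)
        state.x, state.amp_z, state.amp_div = x_next, z, div
    return state.x


# ---------------------------------------------------------------------------
# full unrolled passes
# ---------------------------------------------------------------------------

def _apply_projector(projector, x_tilde: np.ndarray, residual: bool) -> np.ndarray:
    out = projector(x_tilde)
    return x_tilde + out if residual else out


def run_unrolled(scheme: str, projectors, model: meas.MeasurementModel,
                 y: np.ndarray, T: int, *, coeffs: MemoryCoefficients | None = None,
                 mu: float | None = None, residual: bool = False,
                 keep_tildes: bool = False, amp_seed: int = 0,
                 demun_via: str = "conv1x1") -> ReconstructionTrace:
    """Execute T unrolled steps of the chosen scheme and return the trace.

    ``projectors`` is a single callable (shared across steps) or a sequence
    of T callables, each mapping image(s) to image(s) of the same shape.
    Starting point is x_0 = 0.
    """
    if scheme not in SCHEMES:
        raise ConfigurationError(f"scheme must be one of {SCHEMES}, got {scheme!r}")
    if T < 1:
        raise ConfigurationError(f"T must be >= 1, got {T}")
    if callable(projectors):
        projectors = [projectors] * T
    if len(projectors) != T:
        raise ConfigurationError(f"need {T} projectors, got {len(projectors)}")
    if scheme == "demun":
        if coeffs is None:
            raise ConfigurationError("scheme 'demun' requires coefficients")
        if coeffs.T < T:
            raise ConfigurationError(f"coefficients cover {coeffs.T} steps, need {T}")
    elif scheme in ("pgd", "nesterov") and mu is None:
        raise ConfigurationError(f"scheme {scheme!r} requires a step size mu")

    y = np.asarray(y, dtype=np.float64)
    shape = y.shape[:-1] + (model.side, model.side)
    state = IterateState(y=y, x=np.zeros(shape), T=T)
    gammas = nesterov_gammas(T) if scheme == "nesterov" else None

    xs, tildes = [], []
    for i in range(T):
        state.i = i
        if scheme == "pgd":
            x_tilde = pgd_step(state, model, mu)
        elif scheme == "nesterov":
            x_tilde = nesterov_step(state, model, mu, gammas[i])
        elif scheme == "amp":
            proj = projectors[i]
            x_tilde, z = amp_step(state, model)
            eta = lambda u: _apply_projector(proj, u, residual)  # noqa: E731
            state.amp_div = mc_divergence(eta, x_tilde, seed=amp_seed * 1000 + i)
            state.amp_z = z
        else:  # demun
            state.grads.append(_gradient(model, y, state.x))
            x_tilde = demun_step(state, coeffs, via=demun_via)
        x_next = _apply_projector(projectors[i], x_tilde, residual)
        state.x_prev = state.x
        state.x = x_next
        xs.append(x_next)
        if keep_tildes:
            tildes.append(x_tilde)
    return ReconstructionTrace(xs=xs, x_tildes=tildes if keep_tildes else None)


# ---------------------------------------------------------------------------
# trainable end-to-end network
# ---------------------------------------------------------------------------

class UnrolledNetwork:
    """An end-to-end trainable unrolled reconstruction network.

    Holds T DnCNN projectors (independent per step unless ``share_weights``)
    plus the scheme's trainable scalars: all memory coefficients for
    ``scheme="demun"``, a single shared step size mu for ``"pgd"`` and
    ``"nesterov"``, and mu with a stop-gradient Onsager correction for
    ``"amp"``.  ``forward_batch`` records a tape; ``backward_batch``
    accumulates gradients into every `Param` for an Adam step.

    DeMUN coefficients initialize at the PGD view with step size
    ``init_mu`` (default: 1/sigma_max(A)^2 so the initial network is a
    convergent gradient scheme).
    """

    def __init__(self, model: meas.MeasurementModel, T: int,
                 projector_config: ProjectorConfig, scheme: str = "demun",
                 share_weights: bool = False, seed: int = 0,
                 init_mu: float | None = None):
        if scheme not in SCHEMES:
            raise ConfigurationError(f"scheme must be one of {SCHEMES}, got {scheme!r}")
        if T < 1:
            raise ConfigurationError(f"T must be >= 1, got {T}")
        self.model = model
        self.T = T
        self.scheme = scheme
        self.config = projector_config
        self.residual = projector_config.residual
        self.share_weights = share_weights
        if share_weights:
            shared = DnCNN(projector_config, seed=seed)
            self.projectors = [shared] * T
        else:
            self.projectors = [DnCNN(projector_config, seed=seed + 17 * s)
                               for s in range(T)]
        mu0 = init_mu if init_mu is not None else 1.0 / model.spectral_norm_sq()
        self.mu = Param(np.array([mu0]))
        if scheme == "demun":
            self.alphas = Param(np.ones(T))
            self.betas = [Param(np.zeros(i + 1)) for i in range(T)]
            for i in range(T):
                self.betas[i].value[i] = mu0
        else:
            self.alphas = None
            self.betas = None
        self._gammas = nesterov_gammas(T)

    # -- parameters ---------------------------------------------------------

    @property
    def params(self) -> list[Param]:
        if self.share_weights:
            proj_params = self.projectors[0].params
        else:
            proj_params = [p for net in self.projectors for p in net.params]
        if self.scheme == "demun":
            return proj_params + [self.alphas] + self.betas
        return proj_params + [self.mu]

    @property
    def buffers(self) -> list:
        nets = [self.projectors[0]] if self.share_weights else self.projectors
        return [b for net in nets for b in net.buffers]

    def set_buffers(self, arrays: list):
        nets = [self.projectors[0]] if self.share_weights else self.projectors
        pos = 0
        for net in nets:
            k = len(net.buffers)
            net.set_buffers(arrays[pos:pos + k])
            pos += k

    def coefficients(self) -> MemoryCoefficients:
        """Current update coefficients, realized for any scheme that has a
        fixed memory view (demun or pgd)."""
        if self.scheme == "demun":
            return MemoryCoefficients(
                alphas=self.alphas.value.copy(),
                betas=[b.value.copy() for b in self.betas],
            )
        if self.scheme == "pgd":
            return MemoryCoefficients.pgd_view(self.T, float(self.mu.value[0]))
        raise ConfigurationError(
            f"scheme {self.scheme!r} has no static memory-coefficient view"
        )

    # -- forward ------------------------------------------------------------

    def forward_batch(self, y: np.ndarray, train: bool = False):
        """Run the unrolled pass on (N, m) measurements.

        Returns (xs, tape): xs = [x_1..x_T] each (N, side, side); the tape
        carries everything the reverse sweep needs.
        """
        model = self.model
        N = y.shape[0]
        x = np.zeros((N, model.side, model.side))
        xs_all = [x]           # x_0 .. x_T
        tildes, proj_tapes, gs, gzs, divs, zs = [], [], [], [], [], []
        mu = float(self.mu.value[0])
        amp_z, amp_div = None, 0.0
        for i in range(self.T):
            if self.scheme == "demun":
                g = _gradient(model, y, x)
                gs.append(g)
                x_tilde = self.alphas.value[i] * x
                for j in range(i + 1):
                    x_tilde = x_tilde + self.betas[i].value[j] * gs[j]
            elif self.scheme == "pgd":
                g = _gradient(model, y, x)
                gs.append(g)
                x_tilde = x + mu * g
            elif self.scheme == "nesterov":
                x_prev = xs_all[i - 1] if i >= 1 else np.zeros_like(x)
                z = x + self._gammas[i] * (x - x_prev)
                gz = _gradient(model, y, z)
                gzs.append(gz)
                x_tilde = z + mu * gz
            else:  # amp (stop-gradient Onsager correction)
                z = y - meas.forward(model, x)
                if amp_z is not None:
                    z = z + amp_z * (amp_div / model.m)
                g = meas.adjoint(model, z)
                gs.append(g)
                x_tilde = x + mu * g
                eta = lambda u: _apply_projector(  # noqa: E731
                    self.projectors[i], u, self.residual)
                amp_div = mc_divergence(eta, x_tilde, seed=1000 + i) / N
                amp_z = z
                zs.append(z)
                divs.append(amp_div)
            p, tape = self.projectors[i].forward(x_tilde, train=train)
            x = x_tilde + p if self.residual else p
            xs_all.append(x)
            tildes.append(x_tilde)
            proj_tapes.append(tape)
        tape = dict(xs_all=xs_all, tildes=tildes, proj_tapes=proj_tapes,
                    gs=gs, gzs=gzs, mu=mu)
        return xs_all[1:], tape

    # -- backward -----------------------------------------------------------

    def backward_batch(self, loss_grads: list, tape: dict):
        """Reverse sweep; ``loss_grads[i]`` is dL/dx_{i+1}, shape (N, side, side)."""
        model = self.model
        T = self.T
        xs_all, gs, gzs = tape["xs_all"], tape["gs"], tape["gzs"]
        mu = tape["mu"]
        dxs = [np.zeros_like(xs_all[0]) for _ in range(T + 1)]
        dG = [np.zeros_like(xs_all[0]) for _ in range(T)]
        for i in reversed(range(T)):
            dx_in = dxs[i + 1] + loss_grads[i]
            dxt = self.projectors[i].backward(dx_in, tape["proj_tapes"][i])
            if self.residual:
                dxt = dxt + dx_in
            if self.scheme == "demun":
                self.alphas.grad[i] += float(np.sum(dxt * xs_all[i]))
                for j in range(i + 1):
                    self.betas[i].grad[j] += float(np.sum(dxt * gs[j]))
                    dG[j] += self.betas[i].value[j] * dxt
                dxs[i] += self.alphas.value[i] * dxt
                # g_i = A^T(y - A x_i): all uses of g_i are now accounted for
                dxs[i] -= meas.adjoint(model, meas.forward(model, dG[i]))
            elif self.scheme == "pgd":
                self.mu.grad[0] += float(np.sum(dxt * gs[i]))
                dxs[i] += dxt - mu * meas.adjoint(model, meas.forward(model, dxt))
            elif self.scheme == "nesterov":
                self.mu.grad[0] += float(np.sum(dxt * gzs[i]))
                dz = dxt - mu * meas.adjoint(model, meas.forward(model, dxt))
                gamma = self._gammas[i]
                dxs[i] += (1.0 + gamma) * dz
                if i >= 1:
                    dxs[i - 1] -= gamma * dz
            else:  # amp, Onsager correction held constant
                self.mu.grad[0] += float(np.sum(dxt * gs[i]))
                dxs[i] += dxt - mu * meas.adjoint(model, meas.forward(model, dxt))

    # -- inference ----------------------------------------------------------

    def reconstruct(self, y: np.ndarray, keep_tildes: bool = False) -> ReconstructionTrace:
        """Eval-mode unrolled pass on (m,) or (N, m) measurements."""
        single = y.ndim == 1
        yb = y[None] if single else y
        xs, tape = self.forward_batch(yb, train=False)
        if single:
            xs = [x[0] for x in xs]
            tildes = [t[0] for t in tape["tildes"]]
        else:
            tildes = tape["tildes"]
        return ReconstructionTrace(xs=xs, x_tildes=tildes if keep_tildes else None)
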