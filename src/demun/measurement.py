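"""Linear measurement operators for compressive imaging, y = A x* + w.

Two operator families are provided:

* dense i.i.d. Gaussian matrices with entries N(0, 1/m), the classical
  compressed-sensing ensemble (columns have unit expected norm), and
* undersampled 2-D DCT operators A = S·F, where F is the orthonormal
  type-II 2-D DCT on side×side images and S keeps m of the n coefficient
  rows.  The DCT operator is applied matrix-free (transform + gather) and
  satisfies A·Aᵀ = I exactly up to float rounding.

Images are square (n = side²) and vectorized in row-major (C) order; the
same ordering is used by ``forward`` and ``adjoint`` so the adjoint
identity ⟨Ax, r⟩ = ⟨x, Aᵀr⟩ holds to float tolerance.  All constructions
are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.fft

from .exceptions import ConfigurationError, ShapeError, UndefinedSNRError

__all__ = [
    "MeasurementModel",
    "NoiseSpec",
    "ImagePair",
    "make_gaussian_model",
    "make_dct_model",
    "forward",
    "adjoint",
    "add_noise",
    "input_snr_db",
]

DCT_PATTERNS = ("uniform", "low_freq")


@dataclass(frozen=True)
class MeasurementModel:
    """A realized linear operator A ∈ R^{m×n} acting on side×side images.

    ``kind`` is ``"gaussian"`` (dense matrix stored in ``matrix``) or
    ``"dct"`` (matrix-free; ``rows`` holds the kept coefficient indices in
    the row-major flattening of the 2-D DCT coefficient grid).
    """

    kind: str
    side: int
    m: int
    seed: int
    matrix: np.ndarray | None = field(default=None, repr=False)
    rows: np.ndarray | None = field(default=None, repr=False)
    pattern: str | None = None

    @property
    def n(self) -> int:
        return self.side * self.side

    @property
    def sampling_rate(self) -> float:
        return self.m / self.n

    def dense(self) -> np.ndarray:
        """Materialize A as a dense (m, n) array (audit / small problems)."""
        if self.kind == "gaussian":
            return self.matrix
        # rows of the orthonormal 2-D DCT: apply the transform to the
        # identity basis one image at a time
        eye = np.eye(self.n).reshape(self.n, self.side, self.side)
        coeffs = scipy.fft.dctn(eye, type=2, norm="ortho", axes=(-2, -1))
        return coeffs.reshape(self.n, self.n)[:, self.rows].T.copy()

    def spectral_norm_sq(self, iters: int = 50) -> float:
        """Estimate σmax(A)² by power iteration on AᵀA (deterministic)."""
        if self.kind == "dct":
            return 1.0  # rows of an orthonormal matrix
        rng = np.random.default_rng(0)
        v = rng.standard_normal(self.n)
        v /= np.linalg.norm(v)
        for _ in range(iters):
            w = self.matrix.T @ (self.matrix @ v)
            nw = np.linalg.norm(w)
            if nw == 0:
                return 0.0
            v = w / nw
        return float(v @ (self.matrix.T @ (self.matrix @ v)))


@dataclass(frozen=True)
class NoiseSpec:
    """Additive white Gaussian measurement noise w ~ N(0, σ²I)."""

    sigma: float
    seed: int = 0

    def __post_init__(self):
        if self.sigma < 0:
            raise ConfigurationError(f"sigma must be >= 0, got {self.sigma}")


@dataclass(frozen=True)
class ImagePair:
    """A ground-truth image (side×side, values in [0,1]) and its measurements."""

    x: np.ndarray
    y: np.ndarray

    @classmethod
    def measure(
        cls, model: MeasurementModel, x: np.ndarray, noise: NoiseSpec | None = None
    ) -> "ImagePair":
        y = forward(model, x)
        if noise is not None:
            y = add_noise(y, noise)
        return cls(x=np.asarray(x, dtype=np.float64), y=y)


def _check_geometry(side: int, sampling_rate: float) -> int:
    if side < 2:
        raise ConfigurationError(f"side must be >= 2, got {side}")
    if not 0 < sampling_rate <= 1:
        raise ConfigurationError(
            f"sampling_rate must lie in (0, 1], got {sampling_rate}"
        )
    n = side * side
    m = int(round(sampling_rate * n))
    if m < 1:
        raise ConfigurationError(
            f"sampling_rate {sampling_rate} yields zero measurements for n={n}"
        )
    if m > n:
        raise ConfigurationError(f"m={m} exceeds n={n}")
    return m


def make_gaussian_model(side: int, sampling_rate: float, seed: int) -> MeasurementModel:
    """Dense Gaussian operator with i.i.d. entries Aij ~ N(0, 1/m)."""
    m = _check_geometry(side, sampling_rate)
    n = side * side
    rng = np.random.default_rng(seed)
    A = rng.standard_normal((m, n)) / np.sqrt(m)
    return MeasurementModel(kind="gaussian", side=side, m=m, seed=seed, matrix=A)


def _dct_row_order(side: int, pattern: str, seed: int, m: int) -> np.ndarray:
    n = side * side
    if pattern == "uniform":
        rng = np.random.default_rng(seed)
        rows = np.sort(rng.choice(n, size=m, replace=False))
    elif pattern == "low_freq":
        u, v = np.meshgrid(np.arange(side), np.arange(side), indexing="ij")
        # diagonal (zig-zag style) ordering: lowest spatial frequencies first
        order = np.lexsort((v.ravel(), u.ravel(), (u + v).ravel()))
        rows = np.sort(order[:m])
    else:
        raise ConfigurationError(
            f"pattern must be one of {DCT_PATTERNS}, got {pattern!r}"
        )
    return rows.astype(np.intp)


def make_dct_model(
    side: int, sampling_rate: float, pattern: str = "uniform", seed: int = 0
) -> MeasurementModel:
    """Undersampled orthonormal 2-D DCT operator A = S·F (matrix-free)."""
    m = _check_geometry(side, sampling_rate)
    rows = _dct_row_order(side, pattern, seed, m)
    return MeasurementModel(
        kind="dct", side=side, m=m, seed=seed, rows=rows, pattern=pattern
    )


def _as_image_batch(model: MeasurementModel, x: np.ndarray) -> tuple[np.ndarray, bool]:
    """Normalize x to (N, side, side); return (batch, was_single)."""
    x = np.asarray(x, dtype=np.float64)
    side, n = model.side, model.n
    if x.ndim == 1:
        if x.size != n:
            raise ShapeError("signal", (n,), x.shape)
        return x.reshape(1, side, side), True
    if x.ndim == 2 and x.shape == (side, side):
        return x.reshape(1, side, side), True
    if x.ndim == 2 and x.shape[1] == n:
        return x.reshape(-1, side, side), False
    if x.ndim == 3 and x.shape[1:] == (side, side):
        return x, False
    raise ShapeError("signal", (side, side), x.shape)


def forward(model: MeasurementModel, x: np.ndarray) -> np.ndarray:
    """Apply A. Accepts a single image/vector or a batch; returns (m,) or (N, m)."""
    batch, single = _as_image_batch(model, x)
    if model.kind == "gaussian":
        y = batch.reshape(len(batch), model.n) @ model.matrix.T
    else:
        coeffs = scipy.fft.dctn(batch, type=2, norm="ortho", axes=(-2, -1))
        y = coeffs.reshape(len(batch), model.n)[:, model.rows]
    return y[0] if single else y


def adjoint(model: MeasurementModel, r: np.ndarray) -> np.ndarray:
    """Apply Aᵀ to a residual; returns image-shaped (side, side) or (N, side, side)."""
    r = np.asarray(r, dtype=np.float64)
    single = r.ndim == 1
    rb = r.reshape(1, -1) if single else r
    if rb.shape[-1] != model.m:
        raise ShapeError("residual", (model.m,), r.shape)
    if model.kind == "gaussian":
        img = (rb @ model.matrix).reshape(-1, model.side, model.side)
    else:
        coeffs = np.zeros((len(rb), model.n))
        coeffs[:, model.rows] = rb
        img = scipy.fft.idctn(
            coeffs.reshape(-1, model.side, model.side),
            type=2,
            norm="ortho",
            axes=(-2, -1),
        )
    return img[0] if single else img


def add_noise(y: np.ndarray, noise: NoiseSpec) -> np.ndarray:
    """Return y + w with w i.i.d. N(0, σ²); σ=0 returns y unchanged bit-exactly."""
    if noise.sigma == 0:
        return y
    rng = np.random.default_rng(noise.seed)
    return y + noise.sigma * rng.standard_normal(y.shape)


def input_snr_db(
    model: MeasurementModel, images: np.ndarray, noise: NoiseSpec
) -> float:
    """Input SNR in dB: 10·log10( mean‖Ax‖² / (m σ²) ) over the image set."""
    images = np.asarray(images, dtype=np.float64)
    if images.ndim == 2:
        images = images[None]
    if images.size == 0:
        raise ConfigurationError("image set is empty")
    if noise.sigma <= 0:
        raise UndefinedSNRError("input SNR is undefined for sigma = 0")
    y = forward(model, images)
    signal = float(np.mean(np.sum(y**2, axis=-1)))
    return 10.0 * np.log10(signal / (model.m * noise.sigma**2))
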