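"""Seeded synthetic grayscale image sets and standard image I/O.

Three generator families cover the behaviours an unrolled reconstruction
network meets in practice:

* ``cartoons`` — piecewise-constant scenes of random filled ellipses and
  polygons on a flat background: strong edges and flat regions, the regime
  SSIM is sensitive to;
* ``grf`` — band-limited Gaussian random fields with a power-law amplitude
  spectrum |k|^(-gamma), mimicking the 1/f statistics of natural images
  (gamma = 0 gives white noise);
* ``dct_sparse`` — images that are exactly k-sparse in the 2-D DCT domain
  before rescaling, a sanity tier on which DCT-operator recovery is nearly
  trivial.

All images are side x side, rescaled into [0, 1], and bit-reproducible
under a fixed seed.  Loaders accept PNG directories, .npy stacks and HDF5
stacks; RGB inputs are converted to grayscale with ITU-R BT.601 luma
weights (0.299, 0.587, 0.114).
"""

from __future__ import annotations

import pathlib
from dataclasses import dataclass

import h5py
import imageio.v3 as iio
import numpy as np
import scipy.fft
from skimage.draw import disk as draw_disk
from skimage.draw import polygon as draw_polygon
from skimage.transform import resize

from .exceptions import ConfigurationError

__all__ = ["ImageSet", "generate", "load_images", "save_images", "split"]

KINDS = ("cartoons", "grf", "dct_sparse")
LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class ImageSet:
    """A stack of side x side grayscale images in [0, 1]."""

    images: np.ndarray          # (N, side, side) float64
    kind: str = "unknown"
    seed: int = 0
    split_tag: str = ""

    def __post_init__(self):
        if self.images.ndim != 3 or self.images.shape[1] != self.images.shape[2]:
            raise ConfigurationError(
                f"images must be (N, side, side), got {self.images.shape}"
            )

    def __len__(self) -> int:
        return len(self.images)

    @property
    def side(self) -> int:
        return self.images.shape[1]


def _rescale01(img: np.ndarray) -> np.ndarray:
    lo, hi = img.min(), img.max()
    if hi - lo < 1e-12:
        return np.zeros_like(img)
    return (img - lo) / (hi - lo)


def _cartoon(rng: np.random.Generator, side: int) -> np.ndarray:
    img = np.full((side, side), rng.uniform(0.0, 0.3))
    for _ in range(rng.integers(3, 8)):
        level = rng.uniform(0.2, 1.0)
        if rng.random() < 0.5:
            r, c = rng.uniform(0, side, 2)
            radius = rng.uniform(side / 10, side / 3)
            rr, cc = draw_disk((r, c), radius, shape=img.shape)
        else:
            verts = rng.integers(3, 7)
            rr_v = rng.uniform(0, side, verts)
            cc_v = rng.uniform(0, side, verts)
            rr, cc = draw_polygon(rr_v, cc_v, shape=img.shape)
        img[rr, cc] = level
    return np.clip(img, 0.0, 1.0)


def _grf(rng: np.random.Generator, side: int, exponent: float) -> np.ndarray:
    noise = rng.standard_normal((side, side))
    spec = np.fft.fft2(noise)
    kx = np.fft.fftfreq(side)[:, None]
    ky = np.fft.fftfreq(side)[None, :]
    k = np.sqrt(kx**2 + ky**2)
    k[0, 0] = 1.0  # leave the DC mode unscaled
    amp = k ** (-exponent)
    img = np.real(np.fft.ifft2(spec * amp))
    return _rescale01(img)


def _dct_sparse(rng: np.random.Generator, side: int, k: int) -> np.ndarray:
    coeffs = np.zeros((side, side))
    flat_idx = rng.choice(side * side, size=k, replace=False)
    coeffs.ravel()[flat_idx] = rng.uniform(0.5, 1.5, size=k) * rng.choice([-1, 1], size=k)
    img = scipy.fft.idctn(coeffs, type=2, norm="ortho")
    return _rescale01(img)


def generate(kind: str, count: int, side: int, seed: int, *,
             grf_exponent: float = 1.0, sparsity: int = 8,
             split_tag: str = "") -> ImageSet:
    """Generate ``count`` seeded side x side images of the given kind."""
    if count <= 0:
        raise ConfigurationError(f"count must be > 0, got {count}")
    if kind not in KINDS:
        raise ConfigurationError(f"kind must be one of {KINDS}, got {kind!r}")
    if side < 2:
        raise ConfigurationError(f"side must be >= 2, got {side}")
    rng = np.random.default_rng(seed)
    imgs = np.empty((count, side, side))
    for idx in range(count):
        if kind == "cartoons":
            imgs[idx] = _cartoon(rng, side)
        elif kind == "grf":
            imgs[idx] = _grf(rng, side, grf_exponent)
        else:
            imgs[idx] = _dct_sparse(rng, side, sparsity)
    return ImageSet(images=imgs, kind=kind, seed=seed, split_tag=split_tag)


def _to_gray01(arr: np.ndarray) -> np.ndarray:
    arr = np.asarray(arr)
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(np.float64) / np.iinfo(arr.dtype).max
    else:
        arr = arr.astype(np.float64)
    if arr.ndim == 3:
        arr = arr[..., :3] @ LUMA_WEIGHTS
    return np.clip(arr, 0.0, 1.0)


def _center_crop_resize(img: np.ndarray, side: int) -> np.ndarray:
    h, w = img.shape
    s = min(h, w)
    top, left = (h - s) // 2, (w - s) // 2
    img = img[top:top + s, left:left + s]
    if s != side:
        img = resize(img, (side, side), anti_aliasing=True)
    return np.clip(img, 0.0, 1.0)


def load_images(path: str | pathlib.Path, side: int) -> ImageSet:
    """Load a PNG directory, a .npy stack, or an HDF5 stack (dataset 'images')."""
    path = pathlib.Path(path)
    if not path.exists():
        raise IOError(f"no such file or directory: {path}")
    if path.is_dir():
        files = sorted(p for p in path.iterdir()
                       if p.suffix.lower() in (".png", ".jpg", ".jpeg", ".tif", ".tiff"))
        if not files:
            raise IOError(f"no image files found in directory {path}")
        imgs = [_center_crop_resize(_to_gray01(iio.imread(f)), side) for f in files]
        stack = np.stack(imgs)
    elif path.suffix == ".npy":
        stack = np.load(path)
    elif path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            stack = f["images"][...]
    else:
        raise IOError(f"unsupported image container: {path}")
    if stack.ndim == 2:
        stack = stack[None]
    if stack.shape[1:] != (side, side):
        stack = np.stack([_center_crop_resize(_to_gray01(im), side) for im in stack])
    return ImageSet(images=np.clip(stack.astype(np.float64), 0.0, 1.0),
                    kind=f"loaded:{path.name}")


def save_images(image_set: ImageSet, path: str | pathlib.Path):
    """Save to .npy or HDF5 (lossless) or a directory of 8-bit PNGs."""
    path = pathlib.Path(path)
    if path.suffix == ".npy":
        np.save(path, image_set.images)
    elif path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            f.create_dataset("images", data=image_set.images)
            f.attrs["kind"] = image_set.kind
            f.attrs["seed"] = image_set.seed
    else:
        path.mkdir(parents=True, exist_ok=True)
        for idx, img in enumerate(image_set.images):
            arr = np.round(img * 255).astype(np.uint8)
            iio.imwrite(path / f"img_{idx:05d}.png", arr)


def split(image_set: ImageSet, fraction: float, seed: int) -> tuple[ImageSet, ImageSet]:
    """Disjoint, exhaustive, seeded train/test split (train gets ``fraction``)."""
    if not 0 < fraction < 1:
        raise ConfigurationError(f"fraction must lie in (0, 1), got {fraction}")
    n = len(image_set)
    n_train = int(round(fraction * n))
    if n_train == 0 or n_train == n:
        raise ConfigurationError(
            f"fraction {fraction} yields a degenerate split of {n} images"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    tr, te = np.sort(order[:n_train]), np.sort(order[n_train:])
    return (
        ImageSet(image_set.images[tr], image_set.kind, image_set.seed, "train"),
        ImageSet(image_set.images[te], image_set.kind, image_set.seed, "test"),
    )
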