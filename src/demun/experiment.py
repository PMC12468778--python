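"""Experiment harness: configs, the Model/Results API, and the ablation grid.

The central objects follow the fit/results convention of statistical
modelling packages:

* :class:`UnrolledModel` — built from an :class:`ExperimentConfig` and a
  training image set; ``fit()`` trains the unrolled network end to end
  (Adam on measurement/image pairs generated on the fly, fresh noise per
  epoch when sigma > 0) and returns
* :class:`UnrolledResults` — the trained network plus the per-epoch loss
  curve, with ``evaluate()`` (per-image PSNR/SSIM and per-step PSNR
  trajectories), ``summary()``, checkpoint ``save()``/``load()`` and
  per-step PSNR plotting.

``train``/``evaluate``/``ablate`` are thin functions over these objects.
Every output artifact is stamped with a hash of the generating config, and
``ablate`` skips cells whose output already exists, making grids resumable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import itertools
import json
import pathlib
import time
import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd
import yaml

from . import loss as loss_mod
from . import measurement as meas
from . import metrics as metrics_mod
from .data_synth import ImageSet, generate
from .exceptions import ConfigurationError
from .nn import Adam
from .projector import ProjectorConfig
from .unroll import UnrolledNetwork

__all__ = [
    "OperatorSpec",
    "TrainSpec",
    "DataSpec",
    "ExperimentConfig",
    "UnrolledModel",
    "UnrolledResults",
    "train",
    "evaluate",
    "ablate",
    "preset_grid",
    "hypothesis_direction_study",
    "adjoint_baseline",
]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OperatorSpec:
    kind: str = "gaussian"              # gaussian | dct
    side: int = 16
    sampling_rate: float = 0.3
    pattern: str = "uniform"            # dct row-selection pattern
    seed: int = 0

    def build(self) -> meas.MeasurementModel:
        if self.kind == "gaussian":
            return meas.make_gaussian_model(self.side, self.sampling_rate, self.seed)
        if self.kind == "dct":
            return meas.make_dct_model(self.side, self.sampling_rate,
                                       self.pattern, self.seed)
        raise ConfigurationError(f"unknown operator kind {self.kind!r}")


@dataclass(frozen=True)
class TrainSpec:
    epochs: int = 12
    batch_size: int = 16
    lr: float = 1e-3
    lr_decay: float = 1.0               # multiplicative per-epoch step decay
    weight_seed: int = 0
    shuffle_seed: int = 0
    noise_seed: int = 100


@dataclass(frozen=True)
class DataSpec:
    kind: str = "cartoons"
    n_train: int = 200
    n_test: int = 64
    seed: int = 0


@dataclass(frozen=True)
class ExperimentConfig:
    """Full, serializable description of one training/evaluation cell."""

    operator: OperatorSpec = OperatorSpec()
    scheme: str = "demun"
    T: int = 3
    projector: ProjectorConfig = ProjectorConfig(L=3, width=24)
    loss: loss_mod.LossSpec = loss_mod.LossSpec()
    sigma: float = 0.0
    train: TrainSpec = TrainSpec()
    data: DataSpec = DataSpec()
    init_mu: float | None = None        # None = 1/sigma_max(A)^2
    share_weights: bool = False

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        for key, sub in (("operator", OperatorSpec), ("projector", ProjectorConfig),
                         ("loss", loss_mod.LossSpec), ("train", TrainSpec),
                         ("data", DataSpec)):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        return cls(**d)

    def to_yaml(self, path: str | pathlib.Path):
        pathlib.Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | pathlib.Path) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(pathlib.Path(path).read_text()))

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def replace(self, **kw) -> "ExperimentConfig":
        return dataclasses.replace(self, **kw)


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

class UnrolledModel:
    """An unrolled reconstruction network specified by a config, bound to a
    training image set, ready to ``fit()``."""

    def __init__(self, config: ExperimentConfig, train_set: ImageSet | np.ndarray):
        images = train_set.images if isinstance(train_set, ImageSet) else np.asarray(train_set)
        if images.shape[1] != config.operator.side:
            raise ConfigurationError(
                f"training images are {images.shape[1]}px but the operator expects "
                f"{config.operator.side}px"
            )
        self.config = config
        self.train_images = images
        self.measurement_model = config.operator.build()
        self.network = UnrolledNetwork(
            self.measurement_model, config.T, config.projector,
            scheme=config.scheme, share_weights=config.share_weights,
            seed=config.train.weight_seed, init_mu=config.init_mu,
        )

    @classmethod
    def from_yaml(cls, path, train_set) -> "UnrolledModel":
        return cls(ExperimentConfig.from_yaml(path), train_set)

    def initial_loss(self) -> float:
        """Configured loss of the untrained network on the training set."""
        from .unroll import ReconstructionTrace

        y = meas.forward(self.measurement_model, self.train_images)
        xs, _ = self.network.forward_batch(y, train=False)
        return loss_mod.evaluate_loss(
            self.config.loss, ReconstructionTrace(xs=xs), self.train_images
        )

    def fit(self, verbose: bool = False) -> "UnrolledResults":
        cfg = self.config
        net = self.network
        weights = cfg.loss.weights(cfg.T)
        images = self.train_images
        n = len(images)
        bs = min(cfg.train.batch_size, n)
        shuffle_rng = np.random.default_rng(cfg.train.shuffle_seed)
        noise_rng = np.random.default_rng(cfg.train.noise_seed)
        opt = Adam(net.params, lr=cfg.train.lr)
        y_clean = meas.forward(self.measurement_model, images)
        log = []
        t0 = time.time()
        for epoch in range(cfg.train.epochs):
            order = shuffle_rng.permutation(n)
            epoch_loss, n_batches = 0.0, 0
            for start in range(0, n, bs):
                idx = order[start:start + bs]
                xb = images[idx]
                yb = y_clean[idx]
                if cfg.sigma > 0:  # fresh noise draw each batch
                    yb = yb + cfg.sigma * noise_rng.standard_normal(yb.shape)
                xs, tape = net.forward_batch(yb, train=True)
                nb = len(idx)
                batch_loss = 0.0
                grads = []
                for i, x_i in enumerate(xs):
                    diff = x_i - xb
                    batch_loss += weights[i] * float(
                        (diff**2).reshape(nb, -1).sum(axis=1).mean())
                    grads.append(weights[i] * 2.0 * diff / nb)
                if not np.isfinite(batch_loss):
                    raise FloatingPointError(
                        f"training diverged at epoch {epoch}: loss={batch_loss}; "
                        f"config hash {cfg.config_hash}"
                    )
                opt.zero_grad()
                net.backward_batch(grads, tape)
                opt.step()
                epoch_loss += batch_loss
                n_batches += 1
            opt.lr *= cfg.train.lr_decay
            log.append(dict(epoch=epoch, loss=epoch_loss / n_batches))
            if verbose:
                print(f"epoch {epoch:3d}  loss {epoch_loss / n_batches:.5g}")
        return UnrolledResults(
            network=net, config=cfg,
            training_log=pd.DataFrame(log),
            fit_seconds=time.time() - t0,
        )


class UnrolledResults:
    """Trained parameters plus diagnostics for one experiment cell."""

    def __init__(self, network: UnrolledNetwork, config: ExperimentConfig,
                 training_log: pd.DataFrame, fit_seconds: float = 0.0):
        self.network = network
        self.config = config
        self.training_log = training_log
        self.fit_seconds = fit_seconds

    @property
    def measurement_model(self) -> meas.MeasurementModel:
        return self.network.model

    def reconstruct(self, y: np.ndarray):
        return self.network.reconstruct(y)

    def evaluate(self, test_set: ImageSet | np.ndarray, sigma: float | None = None,
                 noise_seed: int = 1234) -> pd.DataFrame:
        """Per-image PSNR/SSIM and per-step PSNR on a test set.

        Test measurements are built with the same operator instance used in
        training; noise (sigma defaults to the training sigma) is one fixed
        seeded draw per image.
        """
        images = test_set.images if isinstance(test_set, ImageSet) else np.asarray(test_set)
        sigma = self.config.sigma if sigma is None else sigma
        y = meas.forward(self.measurement_model, images)
        if sigma > 0:
            y = meas.add_noise(y, meas.NoiseSpec(sigma=sigma, seed=noise_seed))
        xs, _ = self.network.forward_batch(y, train=False)
        rows = []
        for k in range(len(images)):
            steps = np.array([metrics_mod.psnr(x[k], images[k]) for x in xs])
            rows.append(dict(
                image=k,
                psnr=float(steps[-1]),
                ssim=metrics_mod.ssim(xs[-1][k], images[k]),
                step_psnr=steps,
                sampling_rate=self.config.operator.sampling_rate,
                sigma=sigma,
                config=self.config.config_hash,
            ))
        return pd.DataFrame(rows)

    def per_step_psnr(self, test_set, sigma: float | None = None) -> np.ndarray:
        """Mean per-step PSNR trajectory over a test set (length T)."""
        rec = self.evaluate(test_set, sigma=sigma)
        return np.stack(rec["step_psnr"].to_numpy()).mean(axis=0)

    def plot_per_step_psnr(self, test_set, ax=None, **kw):
        import matplotlib.pyplot as plt
        curve = self.per_step_psnr(test_set)
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(np.arange(1, len(curve) + 1), curve, marker="o", **kw)
        ax.set_xlabel("projection step i")
        ax.set_ylabel("PSNR (dB)")
        return ax

    def summary(self) -> str:
        cfg = self.config
        lines = [
            "Unrolled reconstruction results",
            "=" * 33,
            f"scheme:         {cfg.scheme} (T={cfg.T}, residual={cfg.projector.residual})",
            f"operator:       {cfg.operator.kind} side={cfg.operator.side} "
            f"rate={cfg.operator.sampling_rate} (m={self.measurement_model.m})",
            f"projector:      DnCNN L={cfg.projector.L} width={cfg.projector.width} "
            f"({self.network.projectors[0].n_params} params/step)",
            f"loss:           {cfg.loss.family} (omega={cfg.loss.omega}, skip={cfg.loss.skip})",
            f"noise sigma:    {cfg.sigma}",
            f"epochs:         {len(self.training_log)} "
            f"({self.fit_seconds:.1f} s)",
            f"config hash:    {cfg.config_hash}",
        ]
        if len(self.training_log):
            lines.append(
                f"train loss:     {self.training_log['loss'].iloc[0]:.5g} -> "
                f"{self.training_log['loss'].iloc[-1]:.5g}"
            )
        return "\n".join(lines)

    # -- checkpointing ------------------------------------------------------

    def save(self, path: str | pathlib.Path):
        """HDF5 checkpoint of all weights plus a JSON config manifest."""
        path = pathlib.Path(path)
        with h5py.File(path, "w") as f:
            f.attrs["manifest"] = json.dumps(self.config.to_dict(), default=str)
            f.attrs["config_hash"] = self.config.config_hash
            for pi, p in enumerate(self.network.params):
                f.create_dataset(f"param_{pi:04d}", data=p.value)
            for bi, b in enumerate(self.network.buffers):
                f.create_dataset(f"buffer_{bi:04d}", data=b)
            f.create_dataset("training_loss", data=self.training_log["loss"].to_numpy())

    @classmethod
    def load(cls, path: str | pathlib.Path, train_set=None) -> "UnrolledResults":
        path = pathlib.Path(path)
        with h5py.File(path, "r") as f:
            cfg = ExperimentConfig.from_dict(json.loads(f.attrs["manifest"]))
            values = [f[k][...] for k in sorted(f.keys()) if k.startswith("param_")]
            buffers = [f[k][...] for k in sorted(f.keys()) if k.startswith("buffer_")]
            losses = f["training_loss"][...]
        model = UnrolledModel(cfg, train_set if train_set is not None
                              else np.zeros((1, cfg.operator.side, cfg.operator.side)))
        for p, v in zip(model.network.params, values):
            p.value[...] = v
        model.network.set_buffers(buffers)
        return cls(network=model.network, config=cfg,
                   training_log=pd.DataFrame({"epoch": np.arange(len(losses)),
                                              "loss": losses}))


# ---------------------------------------------------------------------------
# functional surface
# ---------------------------------------------------------------------------

def train(config: ExperimentConfig, train_set: ImageSet | np.ndarray,
          verbose: bool = False) -> UnrolledResults:
    """Train an unrolled network; returns the fitted results object."""
    return UnrolledModel(config, train_set).fit(verbose=verbose)


def evaluate(results: UnrolledResults, test_set, sigma: float | None = None,
             operator: OperatorSpec | None = None,
             allow_mismatch: bool = False) -> pd.DataFrame:
    """Evaluate a trained network; refuses operator mismatches by default."""
    if operator is not None and operator != results.config.operator:
        if not allow_mismatch:
            raise ConfigurationError(
                f"operator mismatch: trained on {results.config.operator}, "
                f"asked to evaluate under {operator}; pass allow_mismatch=True "
                "to override"
            )
        warnings.warn("evaluating under a different operator than training",
                      stacklevel=2)
    return results.evaluate(test_set, sigma=sigma)


def adjoint_baseline(model: meas.MeasurementModel, y: np.ndarray) -> np.ndarray:
    """The learning-free A^T y reconstruction baseline."""
    return meas.adjoint(model, y)


# ---------------------------------------------------------------------------
# ablation grids
# ---------------------------------------------------------------------------

_AXIS_SETTER = {
    "loss": lambda c, v: c.replace(loss=v),
    "scheme": lambda c, v: c.replace(scheme=v),
    "residual": lambda c, v: c.replace(
        projector=dataclasses.replace(c.projector, residual=v)),
    "depth": lambda c, v: c.replace(
        projector=dataclasses.replace(c.projector, L=v)),
    "rate": lambda c, v: c.replace(
        operator=dataclasses.replace(c.operator, sampling_rate=v)),
    "T": lambda c, v: c.replace(T=v),
    "sigma": lambda c, v: c.replace(sigma=v),
    "side": lambda c, v: c.replace(
        operator=dataclasses.replace(c.operator, side=v)),
}


def preset_grid(name: str) -> dict:
    """Named ablation grids mirroring the study's comparison layouts."""
    if name == "paper-h1":   # four schemes x {last-layer, unweighted intermediate}
        return {
            "scheme": ["demun", "pgd", "nesterov", "amp"],
            "loss": [loss_mod.LossSpec(family="last_layer"),
                     loss_mod.LossSpec(family="weighted_intermediate", omega=1.0)],
        }
    if name == "paper-h3":   # omega sweep plus skip-5 and last-layer
        losses = [loss_mod.LossSpec(family="weighted_intermediate", omega=w)
                  for w in loss_mod.PAPER_OMEGA_GRID]
        losses += [loss_mod.LossSpec(family="skip_L", skip=5),
                   loss_mod.LossSpec(family="last_layer")]
        return {"loss": losses}
    if name == "paper-h4":   # projector-depth sweep
        return {"depth": [3, 5, 10, 15]}
    raise ConfigurationError(f"unknown preset {name!r}")


def apply_tier(config: ExperimentConfig, tier: str | None) -> ExperimentConfig:
    """Cap problem sizes so a cell runs quickly on one CPU."""
    if tier is None:
        return config
    if tier == "toy":
        caps = dict(side=16, T=3, L=3, width=24)
    elif tier == "small":
        caps = dict(side=32, T=5, L=3, width=32)
    else:
        raise ConfigurationError(f"unknown tier {tier!r}")
    op = dataclasses.replace(config.operator, side=min(config.operator.side, caps["side"]))
    proj = dataclasses.replace(config.projector,
                               L=min(config.projector.L, caps["L"]),
                               width=min(config.projector.width, caps["width"]))
    return config.replace(operator=op, projector=proj, T=min(config.T, caps["T"]))


def hypothesis_direction_study(seeds=(0, 1, 2), *, side: int = 16, T: int = 5,
                               depth: int = 3, width: int = 24,
                               n_train: int = 200, n_test: int = 64,
                               rate: float = 0.3, epochs: int = 12,
                               verbose: bool = False) -> pd.DataFrame:
    """Toy-scale direction checks for the loss / residual-connection effects.

    For each seed, trains three deep-memory networks under a fixed Gaussian
    operator — last-layer loss, unweighted intermediate loss, and unweighted
    intermediate loss with residual connections — and evaluates mean test
    PSNR alongside the learning-free A^T y baseline.  Returns one row per
    seed with columns psnr_ll, psnr_i1, psnr_i1res, psnr_baseline.  These
    check the *direction* of the intermediate-supervision and residual-
    connection effects at desk scale, not their full-scale magnitudes.
    """
    from .metrics import psnr as psnr_fn

    rows = []
    for seed in seeds:
        train_set = generate("cartoons", n_train, side, seed=seed)
        test_set = generate("cartoons", n_test, side, seed=seed + 100)
        row = {"seed": seed}
        variants = {
            "psnr_ll": (loss_mod.LossSpec(family="last_layer"), False),
            "psnr_i1": (loss_mod.LossSpec(family="weighted_intermediate", omega=1.0), False),
            "psnr_i1res": (loss_mod.LossSpec(family="weighted_intermediate", omega=1.0), True),
        }
        mm = None
        for tag, (lspec, resid) in variants.items():
            cfg = ExperimentConfig(
                operator=OperatorSpec(kind="gaussian", side=side,
                                      sampling_rate=rate, seed=seed + 50),
                scheme="demun", T=T,
                projector=ProjectorConfig(L=depth, width=width, residual=resid),
                loss=lspec,
                train=TrainSpec(epochs=epochs, batch_size=16, lr=1e-3,
                                weight_seed=seed, shuffle_seed=seed + 1),
                data=DataSpec(n_train=n_train, n_test=n_test, seed=seed),
            )
            res = train(cfg, train_set, verbose=verbose)
            row[tag] = float(res.evaluate(test_set)["psnr"].mean())
            mm = res.measurement_model
        y = meas.forward(mm, test_set.images)
        base = adjoint_baseline(mm, y)
        row["psnr_baseline"] = float(np.mean(
            [psnr_fn(base[i], test_set.images[i]) for i in range(len(test_set))]))
        rows.append(row)
        if verbose:
            print(row)
    return pd.DataFrame(rows)


def ablate(grid: dict, base_config: ExperimentConfig, train_set: ImageSet,
           test_set: ImageSet, out_dir: str | pathlib.Path | None = None,
           tier: str | None = None, verbose: bool = False) -> pd.DataFrame:
    """Run the cross-product of ``grid`` axes; returns one summary row per cell.

    Completed cells (identified by config hash under ``out_dir/cells``) are
    skipped on re-run; a failing cell is logged and marked, not fatal.
    """
    axes = list(grid.keys())
    for ax in axes:
        if ax not in _AXIS_SETTER:
            raise ConfigurationError(f"unknown ablation axis {ax!r}")
    cell_dir = None
    if out_dir is not None:
        cell_dir = pathlib.Path(out_dir) / "cells"
        cell_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for values in itertools.product(*grid.values()):
        cfg = base_config
        for ax, v in zip(axes, values):
            cfg = _AXIS_SETTER[ax](cfg, v)
        cfg = apply_tier(cfg, tier)
        label = {ax: getattr(v, "family", v) if ax == "loss" else v
                 for ax, v in zip(axes, values)}
        cell_path = cell_dir / f"{cfg.config_hash}.csv" if cell_dir else None
        if cell_path is not None and cell_path.exists():
            row = pd.read_csv(cell_path).iloc[0].to_dict()
            row["recomputed"] = False
            rows.append(row)
            continue
        try:
            res = train(cfg, train_set, verbose=verbose)
            rec = res.evaluate(test_set)
            row = dict(label, config=cfg.config_hash, n=len(rec),
                       psnr_mean=float(rec["psnr"].mean()),
                       psnr_std=float(rec["psnr"].std(ddof=1)),
                       ssim_mean=float(rec["ssim"].mean()),
                       ssim_std=float(rec["ssim"].std(ddof=1)),
                       status="ok")
        except Exception as exc:  # a failed cell must not abort the grid
            warnings.warn(f"cell {label} failed: {exc}", stacklevel=2)
            row = dict(label, config=cfg.config_hash, status=f"failed: {exc}")
        if cell_path is not None and row.get("status") == "ok":
            pd.DataFrame([row]).to_csv(cell_path, index=False)
        row["recomputed"] = True
        rows.append(row)
    return pd.DataFrame(rows)
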