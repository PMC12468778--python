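import dataclasses

import numpy as np
import pytest

import demun
from demun import (
    ConfigurationError,
    DataSpec,
    ExperimentConfig,
    LossSpec,
    OperatorSpec,
    ProjectorConfig,
    TrainSpec,
    UnrolledModel,
    UnrolledResults,
    ablate,
    evaluate,
    generate,
    preset_grid,
    train,
)


def tiny_config(**kw):
    base = dict(
        operator=OperatorSpec(kind="gaussian", side=16, sampling_rate=0.3, seed=5),
        scheme="demun",
        T=2,
        projector=ProjectorConfig(L=1, width=6, residual=True),
        loss=LossSpec(family="weighted_intermediate", omega=1.0),
        train=TrainSpec(epochs=2, batch_size=16, lr=1e-3),
        data=DataSpec(n_train=32, n_test=8),
    )
    base.update(kw)
    return ExperimentConfig(**base)


@pytest.fixture(scope="module")
def small_sets():
    return (generate("cartoons", 32, 16, seed=0),
            generate("cartoons", 8, 16, seed=1))


class TestConfig:
    def test_yaml_roundtrip(self, tmp_path):
        cfg = tiny_config(sigma=0.05)
        cfg.to_yaml(tmp_path / "c.yaml")
        back = ExperimentConfig.from_yaml(tmp_path / "c.yaml")
        assert back == cfg
        assert back.config_hash == cfg.config_hash

    def test_hash_sensitive_to_any_field(self):
        a, b = tiny_config(), tiny_config(T=3)
        assert a.config_hash != b.config_hash


class TestTraining:
    def test_loss_decreases_on_smoke_run(self, small_sets):
        train_set, _ = small_sets
        res = train(tiny_config(train=TrainSpec(epochs=4, batch_size=16)), train_set)
        log = res.training_log["loss"]
        assert log.iloc[-1] < log.iloc[0]

    def test_different_losses_differ_same_seeds(self, small_sets):
        train_set, _ = small_sets
        a = train(tiny_config(loss=LossSpec(family="last_layer")), train_set)
        b = train(tiny_config(loss=LossSpec(family="weighted_intermediate", omega=1.0)),
                  train_set)
        assert not np.allclose(a.training_log["loss"], b.training_log["loss"])

    def test_demun_initialized_at_pgd_view_matches_pgd_loss(self, small_sets):
        train_set, _ = small_sets
        m_dm = UnrolledModel(tiny_config(scheme="demun"), train_set)
        m_pgd = UnrolledModel(tiny_config(scheme="pgd"), train_set)
        assert abs(m_dm.initial_loss() - m_pgd.initial_loss()) < 1e-9

    def test_divergence_aborts_with_diagnostic(self, small_sets):
        train_set, _ = small_sets
        cfg = tiny_config(init_mu=1e40, T=5,
                          projector=ProjectorConfig(L=0, width=4, residual=True))
        with pytest.raises(FloatingPointError):
            UnrolledModel(cfg, train_set).fit()


class TestEvaluate:
    def test_deterministic_and_counts(self, small_sets):
        train_set, test_set = small_sets
        res = train(tiny_config(), train_set)
        a = res.evaluate(test_set)
        b = res.evaluate(test_set)
        assert len(a) == len(test_set)
        assert np.array_equal(a["psnr"].to_numpy(), b["psnr"].to_numpy())

    def test_noise_degrades_mean_psnr(self, small_sets):
        train_set, test_set = small_sets
        res = train(tiny_config(), train_set)
        clean = res.evaluate(test_set, sigma=0.0)["psnr"].mean()
        noisy = res.evaluate(test_set, sigma=0.1)["psnr"].mean()
        assert clean > noisy

    def test_operator_mismatch_refused(self, small_sets):
        train_set, test_set = small_sets
        res = train(tiny_config(), train_set)
        other = dataclasses.replace(res.config.operator, seed=99)
        with pytest.raises(ConfigurationError):
            evaluate(res, test_set, operator=other)
        with pytest.warns(UserWarning):
            evaluate(res, test_set, operator=other, allow_mismatch=True)

    def test_checkpoint_roundtrip(self, small_sets, tmp_path):
        train_set, test_set = small_sets
        res = train(tiny_config(), train_set)
        res.save(tmp_path / "ckpt.h5")
        loaded = UnrolledResults.load(tmp_path / "ckpt.h5")
        a = res.evaluate(test_set)["psnr"].to_numpy()
        b = loaded.evaluate(test_set)["psnr"].to_numpy()
        assert np.allclose(a, b)


class TestAblate:
    def test_grid_bookkeeping_and_resumability(self, small_sets, tmp_path):
        train_set, test_set = small_sets
        grid = {
            "loss": [LossSpec(family="last_layer"),
                     LossSpec(family="weighted_intermediate", omega=1.0)],
            "rate": [0.2, 0.4],
        }
        table = ablate(grid, tiny_config(), train_set, test_set, out_dir=tmp_path)
        assert len(table) == 4
        assert set(table["status"]) == {"ok"}
        assert table["recomputed"].all()
        # re-run: all four cells come from cache
        table2 = ablate(grid, tiny_config(), train_set, test_set, out_dir=tmp_path)
        assert not table2["recomputed"].any()
        assert np.allclose(table["psnr_mean"], table2["psnr_mean"])
        # delete one cell: only that cell recomputed
        victim = table.iloc[0]["config"]
        (tmp_path / "cells" / f"{victim}.csv").unlink()
        table3 = ablate(grid, tiny_config(), train_set, test_set, out_dir=tmp_path)
        assert table3["recomputed"].sum() == 1

    def test_preset_h1_layout(self):
        grid = preset_grid("paper-h1")
        assert grid["scheme"] == ["demun", "pgd", "nesterov", "amp"]
        fams = [ls.family for ls in grid["loss"]]
        assert fams == ["last_layer", "weighted_intermediate"]

    def test_reproducible_summary_under_identical_config(self, small_sets):
        train_set, test_set = small_sets
        cfg = tiny_config(sigma=0.02)
        a = train(cfg, train_set).evaluate(test_set)
        b = train(cfg, train_set).evaluate(test_set)
        assert np.allclose(a["psnr"], b["psnr"])
        assert np.allclose(a["ssim"], b["ssim"])
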