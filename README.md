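# demun — deep memory unrolled networks for compressive image reconstruction

`demun` reconstructs images from compressive linear measurements
**y = A x\* + w** — the forward model shared by MRI, CT and related
computational-imaging systems — by *unrolling* an iterative algorithm for a
fixed number of steps T and replacing every projection with a trainable
convolutional network (a DnCNN), trained end to end.  It is aimed at
practitioners who want to design such networks without hand-picking the
optimization algorithm, the loss, or the projector depth: the package
bundles the measurement operators, the unrolling schemes, the loss family,
the metrics, and an ablation harness for comparing the design choices.

## The model

Projected gradient descent (PGD) alternates, from x₀ = 0,

```
x̃ᵢ = xᵢ + μ Aᵀ(y − A xᵢ),      xᵢ₊₁ = P_C(x̃ᵢ)
```

where P_C projects onto the (unknown) set of plausible images and is
replaced by a DnCNN per step.  The **deep-memory update** generalizes the
gradient step to a trainable linear combination of the current iterate and
*all* stored gradients,

```
x̃ᵢ = αᵢ xᵢ + Σ_{j≤i} β_{j,i} Aᵀ(y − A xⱼ),
```

equivalently a one-by-one convolution over the channel stack
[xᵢ, g₀, …, gᵢ].  Specific coefficient settings recover PGD, Nesterov
acceleration and AMP exactly, so training lets the data choose the
algorithm.  Projection steps may include a residual connection
(xᵢ₊₁ = x̃ᵢ + P_C(x̃ᵢ)), and training may supervise every step through the
weighted intermediate loss Σᵢ ω^(T−i)‖xᵢ − x*‖², its skip-L variant, or
only the last step.

Because no deep-learning framework is assumed, the conv/batch-norm/ReLU
layers and the reverse-mode sweep through the unrolled iteration are
implemented directly on numpy arrays (`demun.nn`) and verified against
finite differences in the test suite.

## Worked example

```python
import demun
from demun.experiment import ExperimentConfig, OperatorSpec, TrainSpec, DataSpec, train
from demun import ProjectorConfig, LossSpec

train_set = demun.generate("cartoons", 200, 16, seed=0)
test_set  = demun.generate("cartoons", 64, 16, seed=100)

cfg = ExperimentConfig(
    operator=OperatorSpec(kind="gaussian", side=16, sampling_rate=0.3, seed=50),
    scheme="demun", T=5,
    projector=ProjectorConfig(L=3, width=24, residual=True),
    loss=LossSpec(family="weighted_intermediate", omega=1.0),
    train=TrainSpec(epochs=12, batch_size=16, lr=1e-3),
    data=DataSpec(n_train=200, n_test=64),
)
res = train(cfg, train_set)          # UnrolledResults
rec = res.evaluate(test_set)
print(f"PSNR {rec['psnr'].mean():.2f} dB   SSIM {rec['ssim'].mean():.3f}")
```

On one CPU this trains in about a minute and prints

```
PSNR 18.16 dB   SSIM 0.659
```

meaning the trained five-step deep-memory network reconstructs held-out
piecewise-constant test images at a mean peak signal-to-noise ratio of
18.2 dB from 30% Gaussian measurements — roughly 16 dB above the
learning-free Aᵀy backprojection (2.0 dB on the same instance), while
the structural-similarity score of 0.66 indicates the main edge structure
is recovered.  `res.summary()` reports the configuration, parameter counts
and training-loss trajectory; `res.per_step_psnr(test_set)` gives the PSNR
after each intermediate projection.

A thin CLI wraps the same calls:

```bash
demun gen-data --kind cartoons --side 50 --count 1000 --seed 7 --out imgs.h5
demun train --config cfg.yaml --out ckpt.h5
demun eval --ckpt ckpt.h5 --sigma 0.05
demun ablate --preset paper-h1 --tier toy
```

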