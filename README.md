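# r2upp

Recurrent-residual nested U-Net (R2U++) for biomedical image
segmentation, with its comparison baselines (U-Net, R2U-Net, U-Net++),
the hybrid cross-entropy/soft-Dice loss, deep supervision with
multi-depth ensembling, a sliding-window patch pipeline, and a seeded
synthetic-data generator so everything is testable without external
datasets.

The package targets researchers who want a transparent, CPU-friendly
reference implementation of the architecture family: every layer runs on
a small, fully tested numpy reverse-mode autodiff engine that ships with
the package, so there is no deep-learning-framework dependency and every
gradient is verified against finite differences in the test suite.

## The model

The network is a triangular graph of convolution blocks $X^{(m,n)}$,
indexed by pyramid level $m$ (spatial size $= \text{input}/2^m$) and
skip-pathway column $n$.  Column $n=0$ is the encoder; block $X^{(m,n)}$
with $n>0$ receives the channel concatenation of all same-level
predecessors $X^{(m,0..n-1)}$ and the up-sampled output of
$X^{(m+1,n-1)}$:

$$x_i^{m,n} = \begin{cases} x^{m-1,0} & n = 0\\
[\,[x^{m,k}]_{k=0}^{n-1},\, u(x^{m+1,n-1})\,] & n > 0\end{cases}$$

Every block is a **recurrent-residual convolutional layer** (RRCL): two
stacked recurrent convolutional layers (RCL) plus an additive shortcut.
An RCL unfolded to time step $t$ computes

$$O_1 = f(\mathrm{BN}(w^f * x)), \qquad
  O_k = f(\mathrm{BN}(w^f * x + w^r_k * O_{k-1})),\quad k = 2..t,$$

with the feed-forward kernel $w^f$ shared across steps and a fresh
recurrent kernel $w^r_k$ per step, so an RCL holds exactly $t$
convolution weight sets.  With deep supervision a $1{\times}1$
conv + sigmoid head sits at each $X^{(0,q)}$, $q = 1..d$; training
minimizes $L = \sum_{i=1}^{d} \eta_i\, L(Y, P^i)$ with the hybrid
per-head loss

$$L(Y,P) = -\tfrac{1}{N}\sum_{c}\sum_{n}\Big(\mathrm{CE}(y_{n,c},p_{n,c})
 + \tfrac{2\,y_{n,c}\,p_{n,c}}{y_{n,c}^2 + p_{n,c}^2}\Big),$$

and at inference the depth-$q$ sub-models embedded in the graph are
either extracted and run alone or averaged into a multi-depth ensemble.
Evaluation uses Dice $=2|GT\cap PR|/(|GT|+|PR|)$, IoU
$=|GT\cap PR|/|GT\cup PR|$, accuracy, sensitivity and specificity.

## Worked example

Train a scaled-down R2U++ on easy synthetic blobs and segment a held-out
image:

```python
import numpy as np
from r2upp import (NetworkConfig, SyntheticTaskConfig, TrainConfig,
                   build_r2upp, generate, train_val_test_split,
                   train, predict_image, MetricsReport)

data = generate(SyntheticTaskConfig(style="blobs", image_size=64,
                                    n_images=200, noise_sd=0.0, seed=7))
tr, va, te = train_val_test_split(data, (0.8, 0.1, 0.1), seed=1)
net = build_r2upp(NetworkConfig(depth=4, base_filters=(8, 16, 32, 64, 128),
                                time_steps=2), seed=3)
net, hist = train(net, tr, va, TrainConfig(batch_size=8, max_epochs=8,
                                           early_stop_patience=3, seed=3))
prob, mask = predict_image(net, te.records[0].pixels)
report = MetricsReport.from_masks(te.records[0].mask, mask)
print(round(hist["val_loss"][-1], 3), round(report.dice, 3))
```

This prints `-0.887 0.992`: the validation loss after eight epochs and
the test-image Dice overlap — the ensemble of the four supervised heads
recovers the blobs almost perfectly on this noise-free task (mean test
Dice 0.974 across the 20 held-out images).

The same functionality is exposed on the command line:

```bash
r2upp synth --style vessels --n 8 --size 64 --seed 0 --out-dir data/
r2upp count-params --arch r2upp --t 2 --filters 32,64,128,256,512 --summary
r2upp train --config cfg.yaml --out-dir run/
r2upp predict --model run/model.npz --in data/vessels-0000_image.png --out pred.png
r2upp evaluate --pred-dir preds/ --gt-dir masks/
```

At full size (`--filters 32,64,128,256,512 --t 2`) the parameter counter
reports `17,849,764 parameters = 18.0 M`.

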