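# connreg

Variational regularization that improves the **connectivity** of image
segmentations — built for thin, low-contrast structures such as retinal
vessels, pavement cracks and insect antennae, where total-variation-style
penalties erase faint branches and leave gaps in what should be one
connected curve.

## The model

Per-pixel class scores `o` (a network's logits, or any feature map) are
turned into probabilities `u` on the per-pixel simplex
`U = {u ∈ [0,1]^C : Σ_c u_c(x) = 1}` by solving

```
u* = argmin_{u ∈ U}  ⟨−o, u⟩ + ε⟨u, ln u⟩
                    + Σ_{i=1..4} λ_i ⟨u, k_i ∗ (−u)⟩   (directional connectivity)
                    + λ ⟨u, k ∗ (1 − u)⟩               (STD boundary penalty)
```

With all weights zero the solution is the entropic softmax
`u = softmax(o/ε)`. The soft-threshold-dynamics (STD) term, with `k` a
small Gaussian, approximates boundary length weighted by curvature. The
connectivity terms use two-point directional stencils — e.g. the vertical
kernel `k_1` places weight 0.5 on the pixels above and below — and reward
expanding the foreground along the chosen direction, which is what bridges
broken thin structures. Everything is smooth (convolutions and inner
products), so the operator can sit at the end of a differentiable pipeline
(`apply_as_layer` runs a fixed unrolling with no data-dependent control
flow).

Two solvers are provided, both linearizing the concave quadratic part at
the current iterate through its subgradient
`p_t = Σ_i λ_i k_i ∗ (−2u_t) + λ k ∗ (1 − 2u_t)`:

* **fixed point** — `u_{t+1} = softmax((o − p_t)/ε)`;
* **proximal forward–backward (PFB)** — adds a proximity term
  `(τ/2)‖u − u_t‖²` whose per-pixel closed form uses the Lambert W
  function (Winitzki initialization + extended-precision Halley
  refinement), followed by one simplex renormalization. PFB stays stable
  when the indefinite diagonal kernel `k_4` makes the regularizer
  non-concave.

The same connectivity term plugs into a two-phase unsupervised model
(Chan–Vese-style fidelity + TV + connectivity), solved by alternating mean
updates with a primal–dual inner loop.

## Worked example

```python
import numpy as np
from connreg import (RegularizedSoftmax, broken_line,
                     feature_map_from_sample, evaluate_masks)

sample = broken_line(seed=0)                     # 64x64 faint line, 2-px gap
o = feature_map_from_sample(sample, margin=4.0)  # surrogate logits

res = RegularizedSoftmax(o, lambda_std=0.1).fit(method="pfb")
print(res.summary())
```

```
Regularized entropic softmax
======================================
field shape:        64 x 64 x 2
method:             pfb
epsilon:            1
lambda_std:         0.1
lambda_dir:         (0.0, 0.0, 0.0, 0.0)
iterations:         7
converged:          True
final residual:     4.563e-07
final energy:       -3085.060787
```

The solver converged in 7 iterations (both schemes typically need fewer
than 10); the final energy is the value of the objective above at the
returned probabilities. Scoring the thresholded mask against the bridged
ground truth:

```python
report = evaluate_masks(res.mask(), sample.gt, prob=res.probabilities[:, :, 1])
print(f"acc={report.acc:.4f} sen={report.sen:.4f} f1={report.f1:.4f} auc={report.auc:.4f}")
```

```
acc=0.9834 sen=0.9688 f1=0.7848 auc=0.9900
```

Accuracy/sensitivity/F1 are pixel rates with the foreground as positive
class; AUC is the area under the (1 − specificity, sensitivity) curve over
a threshold sweep. The unsupervised model follows the same pattern:

```python
from connreg import TwoPhaseSegmentation
seg = TwoPhaseSegmentation(sample.image, lambda_tv=0.01, lambda_conn=1e-6)
print(seg.fit(seed=0).summary())
```

A command line mirrors the library (`connreg simulate`, `connreg evaluate`,
`connreg reg-softmax`, `connreg segment-unsupervised`); every run writes a
JSON sidecar recording its parameters and seed.

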