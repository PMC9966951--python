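# Methods

## Model

The core object is the regularized entropic softmax on the per-pixel
probability simplex. Given a score field `o : Ω → R^C` (C ≥ 2 classes,
channel 0 = background by convention), the output `u` minimizes

    E(u) = ⟨−o, u⟩ + ε⟨u, ln u⟩
         + Σ_{i=1..4} λ_i ⟨u, k_i ∗ (−u)⟩
         + λ ⟨u, k ∗ (1 − u)⟩        over  u ∈ U,

with `U` the set of fields whose channel values are nonnegative and sum to
one at every pixel. The entropy makes the data part strictly convex and
yields the softmax in closed form when all regularization weights vanish.

The STD term `⟨u, k ∗ (1 − u)⟩` (Gaussian `k`) is a smooth proxy for
boundary length: its integrand `u ⊙ k∗(1−u)` is supported within one
kernel radius of the region boundary and is largest at corners, so the
penalty weights boundary length by curvature. It is summed over all
channels.

The connectivity terms `⟨u, k_i ∗ (−u)⟩` reward foreground expansion. The
four kernels are two-point stencils (vertical, horizontal and the two
diagonals, each with weight 0.5 on a pair of opposite neighbours). For the
vertical kernel the integrand departs from its interior plateau only on
horizontal boundary rows, so the term preferentially extends the structure
vertically; the four directions together let a learning pipeline pick the
dominant orientation. These terms act on the foreground channels only
(default: every channel except 0) — applied to the background channel they
would shrink the foreground instead.

Assumptions: 2-D fields; kernels much smaller than the image; weights
nonnegative and of moderate size (the entropy must dominate the concave
curvature for the fixed-point scheme, see below).

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| `epsilon` | entropy weight / softmax temperature | 1.0 | ε = 1 reproduces the standard softmax; smaller values harden the output |
| `lambda_std` | STD boundary weight | 0.0 | 0.1 is a reasonable scale for unit-scale scores |
| `lambda_dir` | four directional weights | (0,0,0,0) | order: vertical, horizontal, diag45, diag135 |
| kernels | 3×3, Gaussian σ = 1 | — | matches the geometry the regularizers were designed around |
| `tol` | sup-norm of successive iterates | 1e-6 | |
| `max_iter` | iteration cap | 100 | non-convergence is reported, not raised |
| `tau` | PFB proximity constant | 0.1 | see the rate analysis below |
| `unroll` | fixed depth for layer use | 5 | no stopping test, static graph |

All quantities are dimensionless; pixel spacing is the unit of length (the
discrete TV and the inner products are plain sums over pixels).

## Solvers

Both schemes linearize the quadratic (generally concave) regularizer at
the current iterate via

    p_t = Σ_i λ_i k_i ∗ (−2 u_t) + λ k ∗ (1 − 2 u_t).

**Linearized fixed point.** `u_{t+1} = softmax((o − p_t)/ε)`, started at
`u_0 = softmax(o/ε)` (the exact unregularized solution). When the
regularizer is concave the linearization majorizes it and each step solves
the majorizer exactly, so the energy sequence is non-increasing. The 3×3
sampled Gaussian is not an exactly positive-semidefinite convolution (its
1-D DFT dips to ≈ −0.096 at the Nyquist frequency), but the entropy's
ε-strong convexity absorbs the defect: descent is guaranteed whenever
λ · 0.0963 < ε/2, far beyond any weight used here.

**Proximal forward–backward.** Adding `(τ/2)‖u − u_t‖²` to the linearized
objective (without the simplex constraint) gives the per-pixel closed form

    u_{t+1} = (ε/τ) · W( (τ/ε) · exp((o − ε − p_t + τ u_t)/ε) ),

with `W` the principal Lambert branch; the output is strictly positive but
unnormalized, and one final per-pixel renormalization (equivalently a
softmax pass on `ln u`) restores the constraint exactly. Two choices make
the scheme consistent with the fixed-point solver:

* the subgradient `p_t` is evaluated at the **renormalized** current
  iterate (its feasible representative), while the proximity anchor stays
  raw. With this choice the projected PFB fixed point satisfies
  `u = softmax((o − p(u))/ε)` — identical to the fixed-point scheme — so
  the two solvers agree to solver tolerance and both reduce exactly to the
  softmax at zero weights. Evaluating `p_t` at the raw iterate instead
  couples the solution to the raw per-pixel scale `exp((o−p)/ε − 1)` and
  shifts it by O(λ);
* the initializer is `u_0 = exp(o/ε − 1)`, the exact raw fixed point of
  the unregularized proximal iteration (its normalization is
  `softmax(o/ε)`), so the unregularized problem converges in one step.

**Choosing τ.** Differentiating the update shows the iteration contracts
linearly at rate `W/(1+W)` with `W = τ·u_raw/ε`, and at the solution
`u_raw = exp((o − p)/ε − 1)`, so the rate is
`τ·W*/(1 + τ·W*)`, `W* = exp((o − p)/ε − 1)` per pixel. Large τ
(heavy damping) slows convergence roughly in proportion; small τ
approaches the exact linearized solve (as τ → 0 the update tends to
`exp((o − p_t)/ε − 1)` in one step). The default τ = 0.1 keeps the scheme
within its expected ~10-iteration convergence for scores up to |o| ≈ 2 at
ε = 1 while retaining damping; for strongly indefinite directional weights
(large λ₄) a larger τ may be needed for stability.

**Lambert W.** `lambert_w` accepts nonnegative arguments, initializes with
Winitzki's closed-form approximation and refines with Halley steps carried
out in numpy's extended precision (`longdouble`), returning extended
precision. The defining identity `w·e^w = x` then holds to better than
1e-10 in *absolute* terms up to x ≈ 1e6 — a float64 result cannot achieve
that, because at x = 1e6 one ulp of the root already moves `w·e^w` by
~1e-9. The solver path casts back to float64, where ~1e-16 relative
accuracy is ample.

**Differentiable use.** `apply_as_layer` runs a fixed number of
fixed-point iterations with no convergence test, so the map `o → u` is a
static composition of convolutions, exponentials and normalizations and
can be differentiated through by any autodiff framework. Learnable weights
must be kept positive by the caller (e.g. softplus).

## Two-phase unsupervised model

For a grayscale image `f ∈ [0,1]` the model minimizes, over the two-class
simplex with foreground channel `v`,

    ⟨v, f1 − f2⟩ + λ₁ TV(v) + λ₂ ⟨v, k ∗ (−v)⟩,
    f1 = (f − c1)², f2 = (f − c2)²,

alternating (a) mean updates `c1, c2` = `v`-weighted means of `f`, and
(b) a `v`-update in which the concave connectivity term is linearized (the
same device as above) and the remaining convex problem — linear term, a
small entropy smoothing ε, and TV under box constraints — is solved by a
Chambolle–Pock primal–dual loop (step sizes 1/√8, warm-started across
outer iterations). The proximal step of the linear + entropy part is
solved per pixel by safeguarded Newton, with saturated pixels clamped
analytically.

Numerical choices:

* TV is discretized with forward differences, isotropic norm, replicate
  (Neumann) boundary; a unit step across H rows has TV exactly H.
* Convolutions use reflect (symmetric) padding everywhere — zero padding
  would create a spurious boundary signal at the image border.
* The recorded objective uses the two-sided fidelity
  `Σ v·f1 + (1−v)·f2`, which differs from `⟨v, f1 − f2⟩` by the
  v-independent constant `Σ f2` (identical minimizer in `v`) but is also
  minimized by the mean updates, so the recorded sequence is monotone
  across the whole alternating scheme. An outer update that fails to
  decrease it (possible if the inner loop is stopped early) is rejected
  and the solver stops.
* Initialization: threshold `f` at its median; ties are broken by the
  seed — the only randomness in the solver.
* The entropy smoothing defaults to ε = 1e-6: enough to keep the proximal
  step strictly convex and the iterates interior, far too small to move
  the 0.5-threshold decision boundary on any pixel with a visible
  fidelity preference.
* Useful weight ranges on [0,1] images: λ₁ roughly 0.01–1 (beyond that TV
  erases faint structures); λ₂ is exposed down to the 1e-6 scale.

A scale observation worth knowing when tuning λ₂ with the Gaussian kernel:
the per-pixel gradient of the connectivity term is `2 λ₂ (k ∗ v) ≤ 2 λ₂`,
while the fidelity gradient at a background-valued pixel is
`|f1 − f2| ≈ |2f − c1 − c2|·|c1 − c2|` — about 0.09 for a contrast-0.3
structure. Tiny λ₂ values therefore only act on pixels whose fidelity is
already near zero (genuinely ambiguous ones); bridging a gap whose pixels
look like clean background requires λ₂ on the order of the fidelity scale,
at which point the Gaussian kernel's pressure — nearly the same at a gap
pixel as at any structure-adjacent background pixel — inflates the whole
foreground rather than just the gap. A *directional* kernel aligned with
the structure is selective where the Gaussian is not (at a gap pixel of a
horizontal line the horizontal stencil sees foreground on both sides,
`k₂ ∗ v ≈ 0.5`, but ≈ 0 at side pixels), so orientation-matched kernels
are the natural choice when gap closure is the goal; the package exposes
them in the unsupervised model as an option.

## Synthetic data

The generators produce the regimes the regularizers target, with exact
ground truth and full determinism (pure functions of parameters + seed):

* `block_field` — binary rectangles for inspecting kernel responses;
* `broken_line` — a 1–n px thick straight line (four orientations) at
  background level 0.4 plus contrast ≤ ~0.4 ("low contrast" by
  construction), with a centered gap and additive Gaussian noise clipped
  to [0,1]. The ground truth is the **bridged** line: closing the gap is
  the behaviour the connectivity term exists to produce, so it must score
  as correct rather than as error;
* `branching_structure` — a seeded random tree of 1–2 px polylines whose
  contrast fades by 0.8 per generation, emulating vessel-like geometry;
* `feature_map_from_sample` — two-channel surrogate logits
  `±margin·(image − 0.5)`, standing in for a trained network's output with
  controllable confidence.

What they do **not** emulate: realistic texture, spatially correlated
noise, contrast-equalization artefacts, curvature of real cracks/vessels,
or the calibrated-but-imperfect logits a trained network produces. Passing
tests on these fixtures demonstrate the mathematical behaviour of the
operators (convergence, descent, expansion, gap geometry), not performance
on photographs.

## Metrics

Confusion counts treat foreground as the positive class. Accuracy,
precision, sensitivity, specificity and F1 follow their defining ratios;
any 0/0 is returned as NaN and flagged by name, never coerced to 0 or 1.
AUC integrates the (1 − specificity, sensitivity) curve over a fixed sweep
of 257 thresholds on [0,1] by the trapezoid rule with endpoints (0,0) and
(1,1) appended; tests cross-check it against the exact rank statistic
(agreement within 1/128). Connected components use 8-connectivity.

## Limitations

* 2-D only; two-phase model is strictly two-region.
* The PFB scheme's speed depends on the score scale (rate
  `τW*/(1+τW*)` above); very confident logits at large τ converge slowly.
* Semi-positive-definiteness of the kernels is recorded as a modelling
  assumption but neither enforced nor checked; for large λ₄ the energy may
  be unbounded in principle and only the proximity term keeps iterations
  stable.
* The Gaussian-kernel connectivity term in the unsupervised model has no
  spatial selectivity for gap pixels (see the scale observation above); at
  weights small enough to leave clean background untouched it leaves the
  segmentation unchanged.
* Problem sizes throughout the tests are 64×64 (and smaller for oracle
  comparisons): large enough for boundary effects and component topology
  to be nontrivial while keeping the full suite fast.
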