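# Methods

## The counting model

`sonarcount` estimates the number of fish in a low-resolution frame by
density-map regression. Each annotated fish is a point $(r, c)$; the
ground-truth density map places a unit-mass Gaussian stamp (size parameter
$s = 4$, i.e. a 5×5 support, $\sigma = 1$ px) at every point, so the map's
spatial integral equals the count. The network maps an image
$I \in [0,255]^{H_I \times W_I \times 3}$ to a tensor
$\hat Z \in \mathbb{R}^{H \times W \times 2}$ with $H = H_I/d$, $W = W_I/d$
($d$ the backbone's downsampling factor). Channel 1 is the predicted
density map $\hat D$ and the predicted count is
$\hat c = \sum_{ij} \hat D(i,j)$; channel 2 holds per-unit contributions to
the predicted log noise variance, $\log \hat\sigma^2 = \sum_{ij} \hat V(i,j)$.
No pixelwise density loss is used: supervision acts on the integrated
count, so ground-truth maps live at full resolution and predicted maps at
$H \times W$ without any reconciliation.

### Loss terms

All batch reductions are sums over the $K$ batch members, exactly as the
equations are written (learning rates inherit this convention):

- count loss $\;L_c = \sum_k |c_k - \hat c_k|$;
- aleatoric-uncertainty count loss
  $\;L_{cau} = \sum_k |c_k - \hat c_k|\, e^{-s_k} + s_k$, with
  $s_k = \log \hat\sigma_k^2$ the model output (the $e^{-s}$
  parameterization of $|e|/\sigma^2 + \log \sigma^2$, numerically safe
  near $\sigma^2 = 0$). With $s \equiv 0$ it reduces to $L_c$ exactly;
  for a fixed error $e$ the optimum is $s^\* = \ln e$, so the learned
  variance tracks the per-image error;
- ranking hinge $\;L_r = \sum_k \max(0, p'_k - p_k + \epsilon)$ over
  Siamese pair scores $p$ (spatial mean of $\hat D$, i.e. global average
  pooling), margin $\epsilon = 0$;
- entropy balance term
  $\;L_{ieb} = -\sum_k \log(K_{class(k)}/K)\,|c_k - \hat c_k|$ with
  abundance classes $c<50$, $50 \le c < 150$, $c \ge 150$; weight
  $\lambda = 0.1$ when active (larger values let the term dominate).

Nine ablation configurations compose these terms and choose data sources:
(i) $L_c$; (ii) $+\lambda L_{ieb}$; (iii) $L_{cau}$; (iv)
$L_{cau}+\lambda L_{ieb}$; (v) $L_c$ on the augmented set; (vi)
$L_c + L_r$; (vii) $+\lambda L_{ieb}$; (viii) $L_{cau} + L_r$; (ix) all
three. Configurations v–ix train on the augmented labelled set, vi–ix add
$K$ ranked pairs per step, and continuation runs start from the trained
weights of their uni-task counterpart ((v),(vi) from (i); (vii) from (ii);
(viii),(ix) from (iii)).

### Self-supervised ranked pairs

For an unlabelled frame of height $h$ and width $w$ with bounding box
$(x_1, y_1, x_2, y_2)$ (default: the full frame), the subregion series is
the original followed by, for each crop factor
$f \in \{0.25, 0.5, 0.75\}$, the region with rows $[y_1 + f h,\, y_2)$ and
columns $[x_1,\, x_2 - f w)$, randomly translated to a top-left $(u, l)$
with $0 \le u \le f h$, $0 \le l \le f w$, randomly h-flipped, and placed
on a blank frame of the original size. The regions are nested, so every
ordered pair $(S_j, S_k)$, $j < k$ — six per image at the default factors —
satisfies count(second) ≤ count(first) by construction. Pairs are
materialized once (flip/translation drawn at generation time) rather than
re-randomized per epoch, which makes the ordering guarantee and
determinism directly testable. For datasets with only binary presence
labels, pairs are instead drawn with the first member from "fish"-labelled
and the second from "no fish"-labelled images.

## Network

The head is a 1×1 convolution with 2 filters and no activation (negative
densities are permitted and handled by the losses; an optional softplus on
the density channel exists as a config flag, default off). The same
parameters serve the counting branch and both ranking branches, so the
multi-task model has exactly the uni-task parameter count; the second head
channel roughly doubles the head only (< 0.1% of a deep backbone).

Two backbones implement the contract (downsample by $d$, 2-channel head):

- **resnet50** ($d = 32$): standard bottleneck ResNet-50 trunk. Batch
  normalization uses frozen running statistics (fine-tuning-style BN),
  keeping the forward pass deterministic at any batch size. ImageNet
  weights can be loaded from a local archive but are never required.
- **tiny** ($d = 8$, ≈53k parameters): four 3×3 conv blocks (three
  strided). It exists so the full training loop runs on one CPU in
  minutes; all desk-scale experiments use it.

The network layer is a small numpy framework written for this package
(im2col convolution, explicit backward passes, Adam); float64 arithmetic
keeps finite-difference gradient checks tight (≤ 1e-6 relative in tests).

### Numerical choices

- $\log \hat\sigma^2$ is clamped to $[-10, 10]$. The clamp's gradient gate
  is one-sided: only gradients that would push further outside the bound
  are blocked, so a run that overshoots can always return.
- L1-type losses use the sign subgradient (0 at exact ties).
- Counting labels are the integral of the ground-truth density map; with
  boundary-renormalized stamps this equals the annotation count exactly,
  so the count is used directly.
- "Kernel of size 4" has no centre pixel on an even grid; the stamp is
  resolved as the odd $2\lceil s/2\rceil + 1$ support centred on the
  annotation, keeping stamping symmetric and conservation exact.
- Points exactly on a leading crop edge are kept, trailing edge dropped
  (half-open boxes), so disjoint crops partition points without double
  counting.

## Synthetic data

The generator emulates background-removed imaging-sonar frames: fish are
small isotropic Gaussian bumps (radius 3–6 px at 320×576; featureless, as
in sonar), dolphins are larger elongated bumps (at most 4 per frame), nets
are thin bright arcs, and frames vary in brightness and blur. Counts are
drawn from a mixture of a point mass at 0 (weight 0.15) and a log-normal
($\mu = 3.414$, $\sigma = 1$) discretized and clipped to $[0, 450]$,
giving a mean of ≈42 with a long upper tail — a stand-in for a
field-collected, low-count-dominated labelled set, not a reproduction of
any particular histogram. Fish may overlap; the annotation keeps both
points (occlusion is central to the task).

The optional **clutter regime** adds zero-mean speckle with standard
deviation proportional to the fish count (0.25·count grey levels). This
creates genuinely heteroscedastic observations — densely populated frames
are noisier and harder to count — giving the uncertainty head a real
signal. What the synthetic data does *not* model: acoustic physics,
perspective or range-dependent scale, temporal coherence between frames,
annotation error. Passing desk-scale tests therefore demonstrates the
correctness of the machinery and the qualitative behaviour of the method,
not field-data error levels.

## Training protocols

Reference schedule (full scale): Adam, lr $10^{-4}$ dropping to $10^{-5}$
after 200 epochs for from-scratch runs; 300 epochs from scratch, 200 for
continuation runs; batch $K = 10$ labelled images plus $K$ pairs for
multi-task runs; three trials per configuration; the best-validation-MAE
checkpoint is retained (early stopping keeps the best weights rather than
halting). An epoch is one pass over the labelled set; pairs are drawn with
replacement per step. Continuation runs use a fresh optimizer.

Desk-scale preset: 64×112 frames with counts clipped to 80, 300 train /
60 val / 60 test, tiny backbone, 30 epochs, lr $5 \times 10^{-3}$ (chosen
once for the short run; the reference lr is tied to a ~300k-step deep-model
schedule), augmented set at 2× the training set, pair pool of 300 pairs
from 50 unlabelled frames.

**AU warm start.** Training $L_{cau}$ from a random backbone can collapse
into the degenerate fixed point of heteroscedastic regression: the count
prediction stays near-constant while $s$ absorbs the error
($s \to \ln|e|$), after which the damped count gradients never recover the
counting task. Reference-scale training avoids this because AU runs always
start from a feature-bearing (pretrained) backbone. The desk-scale
analogue, used by `train.train_uncertainty_model` and the benchmark, is to
train the plain L1 counter first and continue with the AU loss from those
weights. Loss and data are unchanged; only the initialization protocol
differs.

## Evaluation

MAE and RMSE over the test split; per-subgroup normalised MAE
$\mathrm{NMAE}(g) = \sum_g |c - \hat c| \,/\, \sum_g c$ over the strata
$c<25$, $25 \le c<50$, $50 \le c<150$, $c \ge 150$, and "Noise" (which
takes precedence when a frame carries a noise box covering at least 2% of
the frame — the precedence rule itself is a package choice, configurable);
and the Pearson correlation between $\log \hat\sigma^2$ and $|c - \hat c|$
with a one-tailed p-value ($H_1: r > 0$) from the t-transform of $r$ with
$N - 2$ degrees of freedom. A subgroup whose counts sum to zero has no
defined NMAE and is reported as missing.

## Known limitations

- ResNet-50 here is forward-practical but slow to train in pure numpy;
  the package's trainable path is the tiny backbone. Reference-scale
  error levels (which require the real sonar data, pretrained weights and
  hundreds of deep-model epochs) are out of scope.
- The synthetic count distribution and the noise-subgroup routing rule
  are reasonable reconstructions, not measured properties of field data.
- The exact operation mix that would expand 350 labelled frames to a
  particular augmented-set size is not prescribed; the multiplier is a
  free parameter.
- Whether ranking branches should read only the density channel is an
  open choice; they read channel 1 here.
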