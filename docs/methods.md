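# Methods

## The model

`cellgan` implements adversarial generation of single-cell RNA-seq count
profiles. Let $P_r$ be the distribution of real, library-size-normalized
expression vectors $x \in \mathbb{R}_{\ge 0}^G$ and $P_s$ the distribution
induced by a generator $f_g$ applied to white noise $z \sim
\mathcal{N}(0, I_d)$. Training minimizes the Wasserstein-1 distance between
$P_r$ and $P_s$ through its Kantorovich–Rubinstein dual,

$$W(P_r, P_s) = \sup_{\|f\|_L \le 1} \mathbb{E}_{x \sim P_r} f(x)
  - \mathbb{E}_{x \sim P_s} f(x),$$

with the 1-Lipschitz witness $f_c$ (the critic) approximated by an MLP and
the Lipschitz constraint enforced softly by the gradient penalty
$\lambda\,\mathbb{E}_{\hat x}(\|\nabla_{\hat x} f_c(\hat x)\|_2 - 1)^2$ over
random interpolates $\hat x = \epsilon x_\text{real} +
(1-\epsilon) x_\text{fake}$, $\epsilon \sim U(0,1)$.

Both networks are fully connected: gene order is arbitrary and fixed across
cells, so convolutional weight sharing has nothing to exploit. The generator
stacks FC → batch-norm → ReLU blocks and ends in a **library-size
normalization (LSN) layer**: a final affine map into gene space followed by
ReLU and an exact rescale of each cell to a fixed total count $\varphi$,

$$y_\text{relu} = \mathrm{ReLU}(\bar x W + b), \qquad
  y_\text{out} = \frac{\varphi}{\sum_i (y_\text{relu})_i}\, y_\text{relu}.$$

The LSN layer makes the generator's output satisfy, by construction, the
same row-sum contract as its normalized training data, which removes the
library-size mode from what the adversarial game must learn. A guard
$\varepsilon = 10^{-8}$ in the denominator keeps the (never observed in
practice) all-zero pre-rescale cell finite; such cells are emitted as
all-zero.

Optimization alternates five critic updates with one generator update, using
AMSGrad with $\beta_1 = 0.5$, $\beta_2 = 0.9$. "Steps" are counted in
generator updates throughout.

### Conditional variant

The conditional model generates cells of a requested cluster/cell type while
training on all clusters jointly. The generator replaces each batch-norm
affine pair with one `(scale, shift)` pair **per class** (conditional batch
normalization); running statistics stay shared across classes so that tiny
classes normalize stably. Everything else in the generator is shared, so
expression structure learned from abundant classes transfers to rare ones —
structurally, the only label-dependent generator parameters are the CBN
affines (asserted by a test). The critic conditions by projection:

$$\text{score}(x, y) = w \cdot h(x) + b + \langle v_y, h(x)\rangle + c_y,$$

where $h$ is the final hidden feature vector, $v_y$ a learned per-class
vector and $c_y$ an optional per-class bias (on by default, exposed as a
flag). Per-class output heads over a shared feature space are algebraically
this same form, so the single formulation covers both descriptions of the
architecture. During training, generator labels are drawn from the empirical
class frequencies of the training data (uniform sampling available).

## Numerical core

No deep-learning framework is used: `cellgan.autodiff` is a compact
reverse-mode automatic-differentiation engine over NumPy arrays whose
vector-Jacobian products are themselves differentiable graph nodes, so the
gradient penalty (a norm of a gradient inside a loss) is differentiated
exactly rather than approximated. Its first- and second-order outputs are
validated against finite differences in the test suite. Everything runs in
float64 on one CPU; the intended problem sizes are desk-scale (thousands of
cells, hundreds to thousands of genes).

Numerical conventions worth knowing:

* ReLU uses subgradient 0 at 0; its 0/1 mask is treated as constant during
  double backpropagation (the standard almost-everywhere convention).
* Batch-norm: affine-map → normalization → ReLU, eps $10^{-5}$, running-stat
  momentum 0.99, inference uses running statistics. The critic has no batch
  norm (it would interact with the per-sample gradient penalty).
* AMSGrad uses bias-corrected first/second moments and the non-decreasing
  $\hat v$ maximum.
* The conditional gather (per-class CBN parameters) supports first-order
  gradients only; it never sits on the penalty's second-order path, which
  traverses the critic alone.
* The penalized critic objective is a *biased* Wasserstein estimate: for two
  point masses at distance $d$ the optimum is a critic of slope
  $1 + d/(2\lambda)$, i.e. an objective of $d + d^2/(2\lambda)$ (the
  two-sided penalty trades constraint violation against objective gain).
  The 1-D diagnostic `estimate_wasserstein_1d` therefore defaults to
  $\lambda = 100$, bounding the bias below 2.5% for $d \le 5$, while
  training keeps the literature default $\lambda = 10$, where the bias is
  irrelevant because only the minimax equilibrium matters.

## Preprocessing pipeline

The embedding mirrors the standard Cell Ranger secondary analysis and is the
shared coordinate system for every metric:

1. remove genes expressed in fewer than 3 cells; remove cells expressing
   fewer than 10 genes;
2. rescale every cell to $\varphi = 20{,}000$ total counts;
3. natural logarithm — implemented as $\log(1+x)$ because zeros dominate
   the matrices;
4. select 1,000 highly variable genes by normalized dispersion
   (variance/mean, robustly z-scored with median/MAD inside 20 mean-quantile
   bins; constant or unexpressed genes rank last; ties break by gene index);
5. standardize each selected gene to mean 0, sd 1, clip at ±10 (bounds
   outlier leverage; configurable);
6. PCA, keeping 50 components. Loadings come from an economy SVD; each PC's
   sign is fixed by forcing its largest-magnitude loading positive.

The transform is **fitted on real cells only and then frozen**; generated
cells are projected through it, never refitted. Clustering runs on the PCs:
Louvain modularity optimization (igraph's multilevel algorithm) on a
symmetrized 15-nearest-neighbor Euclidean graph at resolution 0.15, or
k-means with $k = 10$; both seeded, labels relabeled in decreasing cluster
size. Marker genes are the top 5 one-vs-rest upregulated genes (Welch t on
log values; ties by gene index) of the two largest clusters, 10 genes total
when disjoint; duplicates keep their first occurrence.

## Evaluation battery

* **Kernel MMD** between generated and real cells in PC space, with
  $k(x,y) = \sum_i \exp(-\|x-y\|^2/\sigma_i^2)$, $\sigma_i \in \{m/2, m,
  2m\}$, and $m$ the median over the pooled sample of the mean distance to
  the 25 nearest neighbors. The estimator is the biased V-statistic, so
  identical samples give exactly 0; the unbiased variant and an explicit
  bandwidth are exposed as flags since the printed scale depends on both.
* **Real-vs-fake AUC**: five-fold stratified cross-validated ROC AUC of a
  1000-tree random forest (Gini splits, $\sqrt{p}$ features per split,
  leaves grown pure), class sizes equalized by subsampling. Chance level
  (≈0.5) is the ideal for a good generator; a real-vs-real split provides
  the calibration control.
* **Training monitors**, recorded on a held-out set of real test cells
  (3,000 or 10% of cells, whichever is smaller, drawn before training):
  Euclidean distance between per-gene mean expression vectors; fraction of
  zero entries in each matrix; overlap of the two top-1000 HVG sets.
* **Marker correlations**: Pearson correlation matrices of log-scale marker
  expression; constant genes get zeroed correlations with a warning.
* **Joint t-SNE** of real and generated cells embedded simultaneously in
  the shared PC space, for visual inspection only.

## Downsampling / augmentation experiment

One target cluster is downsampled to nested, seeded subsets at fractions
{50, 25, 10, 5, 3, 2, 1, 0.5}% (subset sizes round half-up; floor/ceil are
available because published per-level cell counts for this experiment
design cannot all be reproduced by one rounding rule, so the rule is
treated as a parameter rather than a checkable constant). Three 1000-tree class-weighted random
forests are compared per (level, seed): trained on the downsampled data; on
the downsampled data plus 5,000 with-replacement copies of the kept cells;
and on the downsampled data plus 5,000 generator-produced target-class
cells. All classifiers operate in the PC space fitted on the (downsampled)
real training cells; F1 of the target class is evaluated on a 30% held-out
test set, stratified by cluster, whose target-cluster cells were seen by no
generator at any level — disjointness is asserted at run time, not assumed.
Gaussian-noise upsampling is deliberately not implemented.

The `gan_factory` hook decouples the grid logic from adversarial training: a
factory that trains a conditional model per grid cell is provided, and so is
a cheap *oracle* generator used by the tests and the acceptance script —
a bootstrap of the non-test target-cluster cells with a multinomial re-draw
at $\varphi$ total counts per cell, i.e. a sample from (a smoothed version
of) the true cluster distribution. The oracle isolates the experiment's
logic from GAN training cost; it stands in for a well-trained conditional
generator and marks the upper end of what augmentation can deliver.

## Synthetic data

`cellgan.simulate` plants known structure so every stage is testable without
downloads: negative-binomial counts (dispersion $r = 2$; variance
$\mu + \mu^2/r$), per-gene base means lognormal around 0.5 (sigma 1) so
that expression spans realistic orders of magnitude, per-cell lognormal
library-size factors (sigma 0.35), cluster-specific mean vectors with
disjoint marker blocks multiplied by an 8× fold change in their home
cluster (tests require recovery at ≥4×), and optional correlated gene
blocks driven by a shared per-cell lognormal latent factor. Defaults: 3,000
cells, 500 genes, 3 balanced clusters.

What the simulator does **not** emulate: batch effects, doublets, ambient
RNA, continuous differentiation trajectories, and realistic gene–gene
regulatory topology beyond the optional correlation blocks. Passing tests
on this fixture therefore demonstrate that the machinery learns planted
multi-cluster NB structure at desk scale — not that it reproduces published
performance on real tissue atlases, which were trained at GPU scale.

## Problem sizes and defaults

Desk-scale study conditions used by the tests and the acceptance script,
chosen once: 3,000 cells × 200 genes fixtures; generator hidden sizes
(64, 128), critic (128, 64), latent dimension 32, batch 64, learning rate
5e-4, $\lambda = 10$, 2,000 generator steps for the unconditional
distribution-learning check and 1,500/800 for the conditional one and its
label-shuffled control. Full-scale defaults mirror the published setup:
generator (256, 512, 1024), critic (1024, 512, 256), $\varphi = 20{,}000$,
five critic iterations, $\beta_1 = 0.5$, $\beta_2 = 0.9$. The latent
dimension is not fixed by the source description ("reflect the intrinsic
dimension"); the library default is 100. Batch size, learning rate, and the
gradient-penalty coefficient follow the WGAN-GP literature defaults (128,
5e-4, 10).

## Known limitations

* CPU-only float64 training: fine at desk scale, not meant for 10^5+ cells
  at full architecture.
* Headline metrics reported in the literature for this class of model
  (AUC 0.65/0.52, MMD 0.87/0.03, F1 0.95 → 0.45 → 0.93) came from
  GPU-scale training on the 68k-cell PBMC atlas and are treated as
  reference magnitudes; the package reproduces the *relations* those
  numbers express (generated ≈ real ≪ noise in MMD; augmentation rescues
  rare-cluster F1) on synthetic fixtures.
* The MMD scale depends on estimator variant and bandwidth pooling; compare
  MMDs only within one configuration.
* Checkpoints are a versioned single-file `.npz` archive; no cross-version
  migration.
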