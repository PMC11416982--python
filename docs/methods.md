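# Methods

## Model and protocol

The simulator implements saliency-masked federated averaging. `K` sites hold
label-skewed shards of a classification dataset; the global objective is the
`n_k/n`-weighted sum of local empirical risks. A binary mask `m ∈ {0,1}^d`
over the flattened parameter vector is chosen once, before any training, and
never changes; all subsequent optimisation and communication happen on its
support.

**Saliency.** Connection importance at parameters `θ` is
`s_i = |θ_i · ∂L/∂θ_i|` — the magnitude of the derivative of the loss with
respect to a multiplicative gate `c_i` on connection `i`, evaluated at
`c = 1`. Gradients are accumulated (summed) over a configurable number of
local mini-batches; the default is a single batch, the single-shot
convention. Scores are restricted to the *prunable set* `P`: the weight
matrices of dense and convolutional layers. Biases and normalisation
parameters are never pruned — the standard convention, and the one that
keeps very small models trainable at 95% sparsity.

**Mask construction.** The keep count is
`q = round((1 − sparsity)·|P|)` (round half away from zero), so the reported
sparsity refers to `P`; whole-model density including the always-dense
tensors is reported separately (`Mask.density`). Top-q selection breaks ties
at the boundary by lowest flat index: deterministic, and stable across
processes because the parameter ordering (layer registration order, then
tensor insertion order) is part of the serialized layout.

Protocol modes:

- `sum` — per-site score vectors are summed and one top-q mask is broadcast
  to everyone (the method's default). All sites always contribute.
- `weighted` — `n_k`-weighted mean instead of the sum. The weighted-*mean*
  reading was chosen over the raw weighted sum; the resulting mask is
  invariant to the positive normalisation, so the choice is observationally
  irrelevant for the mask itself.
- `individual` — each site keeps the top-q of its own scores (baseline; no
  exchange).
- `random` — one uniform random keep-set, shared (baseline).
- `dense` — all-ones mask (plain FedAvg).

**Iterative schedule.** The iterative variant walks a strictly decreasing
keep-count schedule `q_1 > … > q_T`, re-scoring with fresh gradients at
`θ ⊙ c_t` and selecting the next top-q *within* the current support, so no
pruned connection is ever revived and a one-step schedule reproduces the
single-shot mask exactly. The default schedule spaces keep counts
geometrically ("exponential"); linear spacing is available. On tiny models,
rounding can collapse adjacent counts; duplicates are merged, so a requested
schedule may shorten.

**Training loop.** Each round `r`: sample `K' ≤ K` distinct sites uniformly
(without replacement within the round, independently across rounds), send
each the current global parameters (masked), train locally for `E` epochs of
mini-batch SGD at learning rate `lr·decay^r`, re-applying the mask after
every optimizer step — with plain SGD this is exactly equivalent to masking
the gradient, which is why SGD is the (only) optimizer — and aggregate the
returned parameters with weights normalised over the *selected* subset.
Weights over the selected subset (rather than all `K`) is the standard
FedAvg practice and the only normalisation that sums to 1 when `K' < K`.
For the individual-mask baseline, aggregation is per-position over the
sites whose mask covers that position; uncovered positions retain their
previous value.

Learning-rate decay is applied once per communication round, not per local
epoch.

## Communication accounting

Transmission is an in-process event with exact byte bookkeeping; there is no
real networking and values are never quantised (everything is float64 in
memory, which keeps runs bitwise reproducible). `value_bytes` and
`index_bytes` (default 4 each) parametrise the simulated wire width.

Two wire encodings are implemented. `csr` — flat sorted-index sparse
encoding over the flattened vector (per-tensor row pointers add nothing for
1-D storage, so CSR degenerates to sorted COO; byte counts are stated for
that realisation): `n·(value_bytes + index_bytes)`. `support_order` — values
only, in ascending support order of the static mask: `n·value_bytes`.
Because the mask is broadcast once and fixed, indices are redundant after
round 0; `csr` is the protocol-faithful default, and reports show both. At
sparsity `s` with equal 4-byte widths the per-payload ratios against a dense
values-only baseline are `2(1−s)` (csr) and `1−s` (support_order); the dense
FedAvg arm itself transmits raw values with no index structure, so its ratio
is exactly 1.

Header/metadata overhead is a separate `header_bytes` parameter and defaults
to 0, so the closed-form ratios hold exactly; one-time costs (the dense
score exchange, `|P|·value_bytes` per site, and the bit-packed mask
broadcast, `⌈d/8⌉` bytes) are logged exactly once per run as their own
ledger entries, and the report shows ratios with and without them plus an
amortisation curve, so either accounting convention is recoverable.

## Partitioning

Non-IID shards are generated by drawing, for each site, a class-proportion
vector `q ~ Dir(α·p)` with uniform prior `p = (1/C, …, 1/C)`, then
allocating each class's samples to sites proportionally to the normalised
draws. Continuous fractions become integer counts by largest-remainder
apportionment per class (exactly conserving, ties to the lowest site
index). The at-least-`min_samples` constraint (default 5) is enforced by
resampling the entire draw with a fresh sub-seed up to 100 times, which
preserves the stated distributional model rather than patching shards post
hoc. `α = 0.3` is the default heterogeneity level; `α → ∞` approaches
identical site distributions and `α → 0` one-class sites. Train/test splits
are unstratified 80/20 within each site (train size `floor(0.8·n_k)`, both
sides forced nonempty).

## Synthetic data

`make_volumes` emulates the structure of smoothed gray-matter density maps
at desk scale: per sample, a unit-variance smoothed Gaussian random field
(smoothing σ = 1.5 grid units), plus a class-specific pattern of
`n_signal_blobs = 3` Gaussian blobs whose locations are fixed per
(seed, class) — so the signal is learnable — scaled by `effect_size`, plus a
per-site scalar intensity offset (`site_shift_sd`), plus unit white noise,
shifted by a +3 baseline and clipped at 0. `effect_size` is therefore the
signal-to-noise amplitude ratio; the default 5.0 with `n = 400` samples on a
16×16×16 grid gives a cleanly linearly separable task, which is the regime
used for the learning-sanity checks. The default grid is 16³ rather than
full scan resolution because the method is architecture-agnostic and small
grids keep the whole suite fast; the same spec generates full-size volumes
if asked.

What the generator does *not* emulate: anatomy, registration or
segmentation artefacts, realistic inter-site covariance, or scanner-specific
noise spectra. Tests passing on these volumes therefore demonstrate the
*mechanics* of the protocol (masking, aggregation, accounting, heterogeneity
response) — not clinical-grade performance on real imaging data.

## Architectures and the numpy kernel

Because every operation needs exact per-parameter gradients and bitwise
reproducibility, the classifiers are built on a small float64 numpy kernel
with manual backpropagation (`sparsefl.nn`): dense, 2-D/3-D convolution
(GEMM via im2col), ReLU, non-overlapping max-pool, global average pool,
layer norm, and a softmax cross-entropy head. Backprop is validated against
central differences in the test suite (relative error < 1e-4 on sampled
coordinates across all layer types). He-normal initialisation, biases at
zero; `build_model(name, input_shape, n_classes, seed)` is deterministic per
seed.

Registry: `tiny-mlp` (one hidden layer, optional layer norm — the workhorse
for tests and the volumetric task, applied to flattened volumes),
`small-cnn-2d` (two conv blocks), and `alexnet3d` — a 3-D AlexNet variant
with the conv channel sequence 64-128-192-192-128. Kernel sizes (3³), the
three 2³ max-pools and the global-average-pool head are this package's
choices; the channel sequence is the defining constraint.

## Numerical and reproducibility choices

- One root seed fans out to named `numpy.random.default_rng` entropy tuples
  (documented in `sparsefl.federation`): initialisation, saliency batches,
  per-round sampling, per-(round, site) batch order, random-mask baseline.
  Arms of an experiment grid share data, partition and initialisation, so
  they differ only in mask construction (common random numbers).
- All aggregation is plain float64 accumulation in site order; the
  FedAvg-equivalence check is bitwise, not approximate.
- The payload encoder refuses parameters that violate their mask (any
  nonzero off support), so silent densification cannot pass unnoticed.
- Degenerate inputs: zero rounds returns the masked initialisation; zero
  local epochs returns the start parameters; empty batch sets, empty local
  training sets, non-finite losses/gradients, heterogeneous layouts and
  layout-hash mismatches all raise with context.

## Defaults

| parameter | default | note |
|---|---|---|
| batch size | 32 | reference protocol |
| learning rate | 0.01 | stable on the synthetic volumetric task (SGD) |
| lr decay / round | 0.998 | reference protocol |
| local epochs | 5 | reference protocol |
| rounds | 200 | reference protocol; 500 available via config; tests and the acceptance script use 30-round runs as their simulation size |
| sparsity grid | 0, .5, .8, .9, .95 | experiment default |
| Dirichlet α | 0.3 | reference heterogeneity level |
| min samples/site | 5 | partition constraint |
| K' | K | all sites per round at desk scale |
| saliency batches | 1 | single-shot scoring |
| value/index bytes | 4/4 | simulated wire widths |

## Known limitations

- Sparsity is simulated by masking dense tensors; there are no sparse
  kernels, so wall-clock speed does not reflect the communication savings
  (which are measured in bytes instead, exactly).
- No secure aggregation, encryption, differential privacy, or real
  transport.
- No prune-and-regrow dynamics and no post-aggregation fine-tuning arm
  (these are compared-against methods, not part of this protocol).
- The individual-mask baseline's aggregation rule (per-position averaging
  over covering sites) is one reasonable choice among several; conclusions
  about that baseline should be read with its aggregation in mind.
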