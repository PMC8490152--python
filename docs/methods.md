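# Methods

## Model

`regformer` predicts multi-track genomic signal, binned at 128 bp, from long
one-hot-encoded DNA sequences. The architecture has three stages:

1. **Convolutional tower with attention pooling.** A stem convolution
   (kernel 15, C/2 channels) followed by further blocks (kernel 5, channels
   growing geometrically from C/2 to C), each block being
   norm → GELU → conv with a residual pointwise convolution. After every
   block the length axis is halved by *attention pooling*: for channels j
   and window positions i,

       h_j = Σ_i exp(x_i·w_j) x_ij / Σ_i exp(x_i·w_j),

   with window 2 and stride 2. The pooling weight matrix `w` is initialized
   to 2·I, which biases the operation toward max pooling; `w = 0` recovers
   average pooling, and scaling `w = α·I` interpolates to exact max pooling
   as α grows. With `conv_blocks` pooling stages the spatial resolution is
   2^conv_blocks bp per position (128 bp at the full-scale setting of 7).

2. **Transformer tower with relative positional encodings.** Multi-head
   self-attention with logits

       a_ij = softmax_j( q_i·k_j / √K + q_i·r_{i−j} + u·k_j + v·r_{i−j} ),

   where r_d = W_R f(d) projects a fixed bank of distance basis functions
   into key space and u, v are learned position-agnostic biases
   (Transformer-XL decomposition). The basis bank divides its feature
   budget equally among three classes — exponential decay
   f_i(r) = 2^(−r/r_half,i) with half-lives log-spaced between 3 and the
   sequence length; dyadic central masks 1[r ≤ 2^i]; and gamma densities —
   and, within each class, between a symmetric f(|d|) and a sign-carrying
   sign(d)·f(|d|) variant, so the model can distinguish upstream from
   downstream.

   The gamma features use shape μ_i²/σ² and rate μ_i/σ² (mean μ_i, variance
   σ²), with μ_i placed linearly from L/n to L and σ = L/(2n); each feature
   is rescaled by its value at the mode so its maximum is 1, since the raw
   density peaks span orders of magnitude across μ_i and would otherwise
   produce badly scaled projections at initialization.

   The relative-distance terms are assembled with a per-row shift gather
   that is tested to agree exactly with the direct O(L²) construction.

3. **Crop and heads.** The outer `crop_bins` positions are trimmed (320 per
   side at full scale: those bins can only see regulatory context on one
   side), then a pointwise expansion (C → 2C, GELU) feeds organism-specific
   linear heads. A softplus keeps every output strictly positive, as
   required for Poisson rates; the full-scale heads are 5,313 human and
   1,643 mouse tracks.

At the full-scale configuration (196,608-bp input, 1,536 channels, 7 conv
blocks, 11 transformer blocks, 8 heads, key 64, value 192, 192 positional
features) the output is 896 bins × 128 bp = 114,688 bp. This configuration
is instantiated and run once in the acceptance suite as a shape/positivity
check; training at that scale is out of scope for a single CPU.

### Numerical substrate

No GPU autodiff framework is part of the dependency set; the package ships a
compact reverse-mode autodiff engine over numpy (`regformer.autodiff`) with
exactly the primitives the model needs (broadcast arithmetic, matmul,
reductions, a tap-wise 1-D convolution that avoids materializing unfolded
windows, the relative-shift gather, indexing). Gradients are verified
against central finite differences for every primitive and end-to-end
through the full model (relative error < 1e−3 on attribution scores, with
float64 weights). The tape is single-use: `backward()` releases each node
as soon as its gradient has propagated, which bounds peak memory during
training. All run-time computation is float32 unless a test requests
float64.

## Training

Poisson negative log-likelihood, mean(λ − y·log λ) over all bins and
tracks; the data-dependent log(y!) constant is dropped, so absolute loss
values are comparable only within this implementation. Adam
(β₁ 0.9, β₂ 0.999, ε 1e−8) with the learning rate ramped linearly from 0
over the warm-up steps and constant afterwards; gradients are clipped to a
bounded global norm beforehand (default 0.2). Training batches alternate
between organisms in fixed order when more than one organism is supplied.
Augmentation applies a uniform random shift of up to ±3 bp (vacated
positions become N, i.e. zero rows) and reverse-complements the sequence
while reversing the targets with probability ½. Every `eval_every` steps a
validation metric (Spearman correlation of gene-level CAGE by default) is
computed and the best-scoring parameter set is retained. Fine-tuning
continues on a single organism at a lower rate (default 1e−4) with the
other organisms' heads frozen; the trunk and the designated head update.

## Evaluation

Per-track Pearson r across all 128-bp bins (zero-variance tracks are
reported as missing, not 0). Gene-level CAGE values sum, over a gene's
unique TSS locations, the bin overlapping each TSS plus its two neighbours;
two TSSs falling in the same bin contribute that bin twice — "unique TSS
locations" is taken literally. Genes with a TSS outside the scored window
(or at its very edge) are excluded and counted. Downstream correlations are
computed across genes per experiment, and across experiments per gene
stratified by tertiles of observed expression variance. Matrices can be
log(1+x)-transformed and standardized to zero mean / unit variance per
experiment across genes.

Test-time augmentation averages eight forward passes. Rather than drawing
the eight augmentations at random, the deterministic set
{−3, −1, +1, +3} × {forward, reverse-complement} is used, with
reverse-orientation outputs reversed back before averaging: reproducibility
was preferred over fidelity to random draws, and the set is closed under
orientation so the averaged prediction is invariant to reverse-complementing
the input.

## Interpretation

* **gradient × input** — |∂(scored output)/∂x| at the reference channel;
  because the input is one-hot this equals gradient × input. The scored
  output is the sum of chosen tracks over the TSS bin triple. Scores are
  computed on the model's native (rate) output scale, not a log scale.
* **attention profile** — the post-softmax attention row at the query bin,
  arithmetic-averaged over all layers and heads; lives at bin resolution.
* **ISM** — region-level: mean over seeded random replacements (default 5)
  of |f(modified) − f(reference)|; saturation: all three substitutions per
  position, signed alt − ref, reference entries exactly 0.
* **window score** — the sum of a contribution track over a 2-kb window
  centered on a candidate element (clipped at sequence edges).

## Enhancer–gene benchmark

auPRC is computed as average precision (rectangular rule) over the ranking
with ties broken deterministically by stable sort on (score descending,
input order); interpolated PR areas are avoided because count-derived scores
tie often. Bootstrap uncertainty follows the 80%-subsample / 100-replicate
protocol without replacement, reporting median and quartiles; single-class
subsamples are skipped and counted. The activity-by-distance baseline
(ABC*) sums activity in a fixed 2-kb window centered on the enhancer and
divides by enhancer–TSS distance; it defaults to a single H3K27ac-like
track with a config switch for the DNase×H3K27ac geometric mean. The
TAD-boundary attention contrast averages attention matrices per sequence
group, reduces each matrix over three disjoint region masks (within-domain,
across-boundary, key-at-boundary column) and compares groups per region
with a two-sided Mann–Whitney U test.

## Variant effects

Variant features are signed per-track (reference − alternative) prediction
differences, averaged over both orientations and shifts of ±3 bp, with two
aggregation modes: whole-sequence sum (population-variant scoring) and a
local mode summing the 4 bins (512 bp) nearest the variant with CAGE tracks
log(1+x)-transformed before differencing. Only SNVs are scored; indels
would require aligning shifted outputs and are out of scope. The per-locus
lasso scales features to training mean 0 / sd 1 (zero-variance features
dropped), chooses the penalty by tenfold cross-validation over a path with
seeded, effect-quantile-stratified fold assignment, and is checked by a
planted-support recovery simulation. The training-free summary takes the
first principal component of the mean-centered selected features and flips
its sign if it correlates negatively with the feature mean, making the score
invariant (up to that fixed sign) to feature scaling conventions.

## Homology-aware splits

Genomes are tiled into 1-Mb regions (final tile per chromosome shorter);
tiles of the two organisms are joined when their summed aligned base pairs
exceed 100 kb (strictly), aggregating alignment blocks per tile pair.
Connected components — found with union–find, tested against a breadth-first
oracle — are assigned atomically to train/validation/test: components are
shuffled in seeded order and each is routed to the split currently furthest
below its target tile-mass fraction. Weighting the random assignment by
component size keeps realized fractions within a couple of percent of the
targets without ever splitting a homologous pair.

## Synthetic regulatory genome

The generator plants a controllable ground truth, not a chromatin
simulation. Each locus carries a central promoter/TSS, optional distal
enhancers, and optional insulators, planted as PWM-sampled motifs on a
uniform background. The CAGE-like rate at the TSS is

    λ_TSS = λ₀ · Π_e (1 + s_e · g(d_e)),    g(d) = 2^(−d / d_half),

with the factor dropped for any enhancer separated from the TSS by an
insulator; the rate profile places λ_TSS in the TSS bin and λ_TSS/2 in each
neighbour. Enhancer strength is s_e = 0.5 × (motif copies), copies 1–12, so
strength is legible from sequence; the same copy number scales the
DNase-like and H3K27ac-like peak rates at the element, giving the model
local evidence for where enhancers are. Defaults: λ₀ = 8 counts/bin (a
strong promoter at desk-scale counts), d_half = 30 kb (regulatory reach of
tens of kb), background rates 0.05–0.2 counts/bin, multiplicative enhancer
action with exponential decay chosen for a simple, exactly reproducible
rate model. Counts are Poisson per 128-bp bin given the rates; rates are a
deterministic function of the annotations and are regenerated bit-for-bit
on dataset reload.

What this emulates: point CAGE signal at TSSs modulated by distal elements,
peak-shaped accessibility/acetylation marks, Poisson counting noise, and
insulator blocking. What it does not: nucleosome structure, replication
timing, mappability artifacts, overdispersion beyond Poisson, TF
cooperativity, or any real genome sequence composition. Tests passing on
this generator therefore demonstrate that the architecture, training loop,
attribution and benchmark code are wired correctly and that the model class
can recover planted long-range structure — not that the full-scale model
reproduces real-data accuracies.

## Long-range recovery experiment

Two matched models are compared: a global-attention model (conv tower +
transformer blocks) and a receptive-field-restricted baseline (the
identical conv tower with zero transformer blocks, analytic receptive
field ≈ 0.8 kb). Both are trained with a two-phase curriculum drawn from
the same grammar:

* **Phase 1 (pretraining / pipeline health):** 16,384-bp loci with the
  grammar's default enhancer count (0–3) at 2–6-kb distances. Cheap steps
  at this length teach motif detection, peak placement, and
  enhancer-to-promoter attention. The held-out split of this phase is the
  pipeline-health measurement: across-loci Pearson r of predicted vs
  observed gene-level CAGE (log(1+x) scale, test-time-augmented
  predictions).
* **Phase 2 (adaptation / the long-range condition):** 131,072-bp loci
  with exactly one enhancer planted uniformly 40–60 kb from the TSS
  (either side), on which all long-range evaluation is performed. The
  trunk is fully convolutional and the positional-basis distance scale is
  pinned to the long-phase pooled length, so the same weights train at
  both lengths.

Optimization at this scale is bimodal across initializations: a run either
discovers the positive enhancer-to-TSS coupling or settles into a flat
(occasionally anti-correlated) solution in which attended enhancer content
only inherits the CAGE-suppression role it plays at enhancer positions.
Three measures address this: residual-branch output projections
(attention out-projection, feed-forward output, conv residual pointwise)
are zero-initialized so each block starts as the identity and local
structure is learned before the attention pathway switches on; the
learning rate is cosine-decayed after warm-up; and phase 1 uses restart
selection — several short runs from different initializations, of which
the one with the best validation Spearman is continued. Conv blocks can
also use LayerNorm instead of BatchNorm (`conv_norm` config) since batch
statistics are poorly defined at batch size 1; the full-scale default
remains BatchNorm with momentum 0.9 and a constant post-warm-up rate.

After training, gradient × input contributions toward the CAGE TSS triple
are summed in 2-kb windows at the planted enhancer and at matched
background windows (mirror position and mirror + 5 kb); groups are
compared with a one-sided Mann–Whitney U test over ≥ 20 held-out long
loci, and the same window scores rank enhancer vs background windows for
an auPRC against a prevalence of 1/3. The restricted model's contribution
strictly beyond its receptive field is asserted to be exactly zero — an
architectural consequence, since every operation in the conv tower is
spatially local. (In the experiment report, an all-tied score set — as the
restricted model produces when every window lies beyond its field — is
summarized by the expected auPRC under random tie-breaking, i.e. the
prevalence.)

Problem sizes for the desk-scale runs (training steps, restart counts,
locus counts, model widths) are set in `LongRangeConfig`; they are the
smallest runs that train the attention pathway to criterion on one CPU,
and the methods above do not depend on them. Even with restart selection,
whether a given seed leaves the flat optimum within this step budget is
stochastic; the experiment reports whatever the selected run achieved, and
the trained-model checks (enhancer-contrast significance and the held-out
pipeline-health correlation) should be read as draws from that outcome
distribution, not as deterministic guarantees. When a run does take off,
the enhancer-vs-background contrast is typically decisive (rank-sum
p < 1e-6 and pair auPRC far above the 1/3 prevalence in our probe runs).

## Degenerate inputs and tie-breaking

* Unknown IUPAC codes (anything outside ACGTN) are rejected with the
  offending position, not silently mapped.
* Shift augmentation pads with all-zero (N) rows rather than wrapping.
* Correlations of zero-variance vectors are reported as missing.
* auPRC of a single-class ranking is undefined and returned as NaN;
  bootstrap replicates that draw one class are skipped and counted.
* distance-stratum edges are half-open [lo, hi); a pair exactly at an edge
  joins the upper stratum.
* The lasso falls back to an intercept-only model when every feature (or
  the response) has zero variance.

## Known limitations

* Training at the full-scale configuration is far outside a single-CPU
  budget; full-scale code paths are exercised by one forward pass only.
* The attention-contrast analysis is validated mechanically (null on
  identical groups; detects a synthetically insulated attention pattern);
  the desk-scale trained models are not claimed to learn insulator biology.
* BatchNorm statistics are single-device; the cross-replica aggregation of
  distributed training reduces to ordinary momentum-0.9 batch norm here.
* Checkpoints are a zip container (JSON config + npz weights) specific to
  this package.
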