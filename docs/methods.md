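# Methods

## The model

`survformer` treats a patient's transcriptome as a sentence whose words are
genes.  Every sample shares the same token vocabulary: gene *i* enters the
encoder as a fixed embedding g⁰ᵢ pretrained on a protein–protein
interaction (PPI) graph and projected into the model width.  What
distinguishes one patient from another is *where* the genes "stand" — the
expression profile — and that information enters exclusively through the
attention logits.  For layer *l* and a head of width *d*, the attention
logit between query gene *i* and key gene *j* of sample *p* is

    α_ij = (gᵢ W^Q)(gⱼ W^K)ᵀ / √(2d)  +  (eᵢ u^Q)(eⱼ u^K)ᵀ / √(2d)

where eᵢ is the (per-gene standardised) expression of gene *i* and u^Q, u^K
are learned projection vectors, per head and shared across layers.  Because
eᵢ is scalar, the second term equals eᵢ·eⱼ·(u^Q·u^K)/√(2d): a rank-one,
sample-specific modulation of the attention matrix.  The value pathway is a
standard learned projection with no positional contribution (untied, in the
spirit of decoupled content/position attention).  Pre-norm residual blocks
with gene-wise feed-forward layers follow; mean pooling over genes yields
the sample embedding (max and attention-weighted pooling are available);
task-specific two-layer heads produce a scalar (regression), class logits
(classification), or *m* interval logits (survival).

### A structural property worth knowing

Since expression enters only through products eᵢ·eⱼ, the network's output
is *exactly invariant* to a global sign flip of the expression vector.
With perfectly sign-symmetric inputs the model therefore cannot rank
patients by any odd (e.g. purely linear single-gene) function of
expression; it excels at interaction-like (even) structure, and it picks up
monotone single-gene effects only through the asymmetry of real expression
distributions (log-transformed FPKM is right-skewed with a floor at zero).
This is a property of the published attention formulation, not of this
implementation, and it shaped both the synthetic-data defaults and the
perturbation probe below.

## Survival likelihood (discretized-time MTLR)

Time is cut at 0 = τ₀ < τ₁ < … < τ_m, with interior boundaries at the
quantiles of the uncensored training event times (default m = 10) and τ_m
at the maximum observed time.  The event-time distribution is encoded by
the m+1 monotone binary label vectors; a configuration scores
exp(Σ_k y_k f_k) given interval logits f, normalised over the m+1 valid
configurations.  An observed event in interval j contributes −log of its
configuration's probability; a censored observation contributes −log of the
total mass of configurations consistent with surviving the censoring time.
The predicted survival curve is S(τ_k) = P(event after interval k), and the
risk score used for concordance is the cumulative incidence mass
Σ_k (1 − S(τ_k)) — a monotone, parameter-free summary.  The likelihood and
its gradient are verified against exhaustive configuration enumeration for
all m ≤ 12 in the test suite.

## Multitask optimization

The composite objective is Σ_t λ_t·L̂_t with λ_t = 1 (the method under
study resolves task conflicts by gradient geometry rather than weight
tuning).  Per batch, each task's loss is backpropagated separately to
obtain per-task gradients of the shared encoder parameters; gradient
surgery (PCGrad) projects task *i*'s gradient onto the normal plane of any
task *j* it conflicts with (vᵢ·vⱼ < 0), in seeded random order against the
original gradients, and the projected vectors are summed.  Task-head
parameters always receive their own task's unmodified gradient.  Samples
with a missing label are masked out of that task's loss only.

Training uses Adam (default lr 1e-4; the synthetic studies below use 2e-3),
a linear warmup over the first 50 steps, global-norm gradient clipping at
5, and early stopping on the validation composite loss with the
best-validation checkpoint restored.  Warmup and clipping were added
because small-cohort runs otherwise diverge or stall in the first epochs;
an optional `min_epochs` floor keeps early stopping from firing inside the
warmup window.

The implementation runs on a compact reverse-mode automatic-differentiation
engine over numpy arrays written for this package (`survformer.nn`), with
single-precision training as the default and float64 available for
gradient checking.  All gradients are verified against central finite
differences in the test suite.

## Gene embeddings

node2vec walks (defaults p = q = 1, walk length 80, 10 walks per node,
window 5) are simulated on the PPI graph; the embedding is obtained by
factorising the walk co-occurrence shifted-PPMI matrix with a truncated
SVD — the closed-form optimum of the skip-gram negative-sampling objective
— which is deterministic given the seed and markedly more stable than
stochastic training on the small corpora that gene-scale graphs produce.
The PPMI shift is 1 (no negative-sampling offset) because larger shifts
zero out the weak co-occurrence contrasts of small dense graphs.  Genes
absent from the graph receive seeded random vectors of scale 1/√d so the
expression matrix, not the graph, dictates the gene universe.  Two ablation
utilities mirror the published comparisons: random initial embeddings, and
embeddings pretrained on a degree-preserving double-edge-swap randomisation
of the graph.

## Attention analysis

Per sample, an edge key→query is drawn wherever any head's post-softmax
weight exceeds 0.01, unioned over heads and layers keeping the maximum
weight; self-edges are excluded by default so degree statistics are not
dominated by the diagonal.  Hubs are genes with out-degree > μ + 2σ,
attractors in-degree > μ + 2σ (strict).  Core genes compare selection
frequencies between two groups: two-sided Fisher's exact test per gene,
Benjamini–Hochberg correction, and absolute proportion ratio > 2 with
pseudocount 0.5/group-size; genes selected in neither group are removed
before correction.  Differential attention compares a per-gene aggregate
score between model variants with Welch's t-test and BH correction; the
default aggregate is the mean attention a gene *receives* as key (averaged
over layers, heads and queries), consistent with attractor semantics —
outgoing and symmetric aggregates are exposed because the choice is not
canonical.  Over-representation of gene lists in named sets uses the
hypergeometric tail with BH correction.

## Synthetic data

The generator emulates the statistical structure the model assumes, at a
desk scale: 600 samples × 120 genes by default.  Six latent factors drive
15-gene co-expression modules (loading 0.9, residual sd 0.45); log-FPKM is
latent × 1.2 plus a per-gene baseline, exponentiated, so log2(FPKM+1) is
right-skewed with a floor at zero.  The gene graph adds dense within-module
wiring (edge probability 0.25) on a scale-free background, tying the
embedding pretraining to the expression structure.  Clinical covariates are
noisy functions of module activities (age and tumor size linear; grade
ordinal; subtype argmax).  Survival times are exponential with log-hazard
β·(two main-effect genes) + γ·(z_a·z_b) on standardised log-expression,
with β = 0.6 and γ = 1.5; the interaction dominates by design because
gene–gene interaction is precisely the structure the attention mechanism is
built to model (and, per the sign-flip property above, the even component
is what any such model can learn), while the main effects exercise the
skew-mediated pathway.  Hazard ratios of e^0.6–e^1.5 per sd are in the
range reported for strong prognostic markers.  Censoring is independent
exponential with its rate solved (Brent) to hit the target fraction
(default 0.3).  The oracle risk achieves held-out concordance ≈ 0.76–0.84
at these defaults, which is the ceiling the model is measured against.

What the generator does *not* emulate: count-level noise (negative
binomial, library-size variation), batch effects, missing clinical data
patterns beyond random masking, and non-proportional hazards.  Passing
tests on this generator therefore show that the pipeline recovers the
structure it targets under clean conditions, not that it matches clinical
performance on real cohorts.

## Problem sizes and numerical choices

The end-to-end studies train a 1-layer, 2-head, d_model = 32 encoder for up
to 35 epochs (batch 64) on the 600 × 120 cohorts — small enough that the
full multi-seed suite runs on a single CPU core in minutes, while still
recovering the planted signal (held-out C-index ≈ 0.66–0.72 across seeds
versus the ≈ 0.8 oracle).  Zero-variance genes get sd clamped to 1 rather
than being dropped, keeping gene indexing aligned with the embedding table.
Duplicate gene rows are collapsed by mean on reading.  Highly variable
genes are ranked on log-transformed (not standardised) values with
lexicographic tie-breaks.  Attention tensors are materialised in batches
(64 samples at a time) because a full cohort's (samples × layers × heads ×
genes²) array is the memory bottleneck.  The 0.01 network threshold is
applied per head before the union over heads and layers.

## Perturbation probe

A gene is perturbed multiplicatively in FPKM space, the stored log/z-score
chain re-applied, and the change in predicted cumulative-incidence risk
recorded per sample.  Because the multiplicative shift is larger in log
space for high-expression samples and module partners are correlated, the
probe produces a positive mean risk shift for the planted interaction gene
in a well-trained model.  The probe measures sensitivity, not causal
attribution: perturbing any gene slightly perturbs every attention row, so
null genes show small but nonzero mean shifts rather than exact zeros.

## Known limitations

- The sign-flip invariance bounds what the architecture can extract from
  symmetric expression distributions; cohorts whose prognostic signal is
  purely linear in a few genes are a worst case.
- node2vec here is the PPMI-SVD closed form, not stochastic SGNS; on large
  sparse graphs the dense co-occurrence matrix (nodes²) would need a sparse
  implementation.
- Harrell's concordance is implemented with strict earlier-time comparable
  pairs; IPCW variants are out of scope (a flag documents the choice).
- Training is single-threaded numpy; cohorts beyond a few thousand samples
  × a few hundred genes call for a GPU framework.
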