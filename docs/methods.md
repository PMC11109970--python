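# Methods

## Model

`gsascore` learns gene set activity scores (GSAS) with an autoencoder whose
bottleneck is structurally tied to a gene set collection. With $n$ genes
and $p$ sets, the encoder weight matrix $W \in \mathbb{R}^{n \times p}$ is
multiplied elementwise by the binary membership mask $M$; the score of set
$j$ for a sample is the pre-activation bottleneck output
$s_j = \sum_g (W \odot M)_{gj} x_g$. The decoder maps $\tanh(s)$ back to
all $n$ genes through a fully connected linear layer with bias. Training
minimizes mean squared reconstruction error with Adam
($\beta_1 = 0.9,\ \beta_2 = 0.999$, no weight decay, no early stopping).

Assumptions: the input matrix is continuous and roughly Gaussian per gene
(VST- or log-transformed upstream; raw counts are out of scope) and is
standardized per gene (mean 0, sd 1, population denominator $n$) before
training or scoring. Standardization of query data happens within the
query dataset, never with training-set moments; genes the model expects
but the query lacks are imputed at 0 — the standardized mean — and the
per-set imputed fraction is reported (warning above 20%, configurable).

The mask is enforced bit-exactly at every optimizer step: gradients are
masked before the Adam update and the weights re-masked after it, so
`max |W ⊙ (1−M)|` is exactly 0 at all times, not merely small.

### Architecture variants

* `geneset` (default): masked encoder → $p$ scores → dense decoder.
* `geneset_dense`: adds a dense decoder hidden layer (default 1000 units).
* `dense_geneset`: adds a per-set hidden layer in the encoder (default 10
  neurons per set), block-masked so each hidden neuron still sees only its
  set's genes; for these variants the reported gene→set weights are the
  first-layer weights aggregated through the second layer.
* `dense_geneset_dense`: both.
* Dropout (when configured; 0.3 is the conventional rate) acts on the
  decoder input, only during fine-tuning, only in training mode.

Open choices the upstream description leaves unstated, fixed here and
exposed as configuration: hidden activation `tanh` (bounded and odd —
consistent with scores whose sign is arbitrary), linear output layer,
encoder bias **off** (so a score is literally a weighted sum of member
genes), decoder bias on. Initialization is a seeded Glorot-style uniform
on unmasked entries, with per-column fan-in equal to the set size.

## Three-step training

1. **Step 1** — for each set independently, a one-neuron autoencoder
   (members → 1 → members) is trained on the member-gene columns; its
   encoder weights are copied into the corresponding masked column. The
   mini-decoders are discarded and the main decoder is untouched. Per-set
   random streams derive from `SeedSequence([master_seed, 1, set_index])`,
   so results do not depend on training order. At convergence the step-1
   score is (up to sign and scale) the first principal component of the
   gene block — verified against an SVD oracle in the tests.
2. **Step 2** — the encoder is frozen *exactly* (its parameters are not
   registered with the optimizer; no float drift) while the decoder trains.
3. **Step 3** — everything unfreezes and fine-tunes.

Defaults: step 1 100 epochs @ lr 1e-2, step 2 50 @ 1e-3, step 3 100 @
1e-4, batch 64, validation fraction 0.2 (optionally stratified, fraction
honored per stratum to the nearest sample). These are sensible desk-scale
values, not a reconstruction of any published schedule. Setting a step's
epochs to 0 skips it, which is how the `step3-only` and `step1+step3`
comparison schedules are expressed. Batches are reshuffled every epoch
from a seeded stream; a fixed seed reproduces the final weights bitwise
(single-threaded numpy).

The model is built over the genes of the input matrix that belong to at
least one gene set: genes outside every set would be dead encoder inputs,
and the transcriptome-wide representativity question is answered by the
redundancy-analysis diagnostic on the *full* matrix rather than by the
decoder.

## Diagnostics

**Replicability** of set $j$: train $\geq 2$ runs differing only in seed,
compute all pairwise Spearman rank correlations of the score vectors over
all samples (train + validation), take the minimum of the absolute values.
Ties get average ranks (training plateaus can create ties); a constant
score vector yields 0, not NaN, so pathological sets get pruned.
Replicability is invariant to per-set sign flips and to any monotone
transform of the scores.

**Pruning** (`prune_by_replicability`, defaults: 6 seeds, threshold 0.7,
one round, iterated rounds optional): train, measure, drop sets below
threshold. The overlap filter is not recomputed after pruning.

A point worth stating explicitly: redundant (near-duplicate) sets lose
replicability only once fine-tuning approaches the optimum. Two bottleneck
neurons wired to the same gene block optimally span that block's top-2
principal subspace, and *where* in the continuum of equivalent rotations a
run lands depends on the seed — that is the mechanism behind duplicate
sets' irreproducible scores. Under the gentle default fine-tune the
duplicates simply stay at their (deterministic) step-1 initialization and
look spuriously replicable. The pruning experiments in the tests and the
acceptance script therefore fine-tune at convergence scale (step 3: 300
epochs @ 1e-3). With that schedule, injected exact duplicates fall to
replicability ≈ 0.5 and are pruned, while disjoint sets stay ≥ 0.999.

**Definition consistency** between two datasets scored by one model: per
set, the profile of Pearson correlations between member-gene expression
and the set's score is computed in each dataset; the consistency is the
Pearson correlation between the two profiles over member genes present in
both (≥ 3 required, otherwise flagged uncomputable). Categories follow
the conventional bands: equivalent > 0.9, high > 0.7, low/intermediate
> 0, opposite < 0. When the datasets share samples, the per-set Pearson
correlation of the scores themselves (score replicability) is also
reported.

**Representativity**: the fraction of variance of the standardized
expression matrix explained by the score matrix in the redundancy-analysis
sense — every gene column regressed on the (centered) score columns by a
rank-revealing least squares, summed fitted variance over summed total
variance. Tested against a brute-force per-gene regression oracle
(agreement to 1e-10) and against `vegan::rda` in R (agreement to 1e-9).
It is monotone under adding score columns and equals 1 when the scores
have full sample rank.

**PC agreement**: top-$k$ principal component score vectors of the
expression and score matrices (centered, SVD), all pairwise $|r|$, plus
each expression-PC's best match. Because a tanh bottleneck makes score
*scales* arbitrary, the variance ordering of score PCs need not mirror the
gene-matrix ordering — a dominant expression PC can surface as a lower
score PC, which is why the diagnostic reports the maximum over all $k$
score PCs.

## Synthetic data

The generator emulates the structure this pipeline consumes: per-set
latent factors $f_j \sim \mathcal{N}(\mu_{\text{stratum}}, 1)$, member
genes $x_g = \sum_{j \ni g} \lambda_{gj} f_j + \varepsilon$ with signed
loadings $\lambda \sim \pm U[0.3, 1]$ (signed, so sets with genes moving
in opposite directions are exercised) and
$\varepsilon \sim \mathcal{N}(0, 1/\mathrm{snr})$; background genes are
pure noise. Defaults — 500 samples, 20 sets × 25 genes, 100 background
genes, snr 3 — give per-gene factor correlations of roughly 0.5–0.9,
comparable to a well-expressed pathway in bulk RNA-seq. Options add
overlapping set pairs (a designated number of consecutive pairs sharing a
fraction of genes, which then load on both factors), pseudo-tissue strata
shifting factor means, and fresh cohorts from the same biology
(`resample_seed`: same memberships and loadings, new samples) for
consistency studies. Output is standardized by default so fixtures enter
the pipeline exactly as real data would.

What the simulation does *not* model: count-level noise, batch effects,
platform/probe artifacts, correlated background structure, non-Gaussian
tails. Passing tests therefore demonstrate the mechanics and the claimed
invariances (mask conservation, freeze exactness, seed determinism,
replicability behavior under redundancy), not performance on real tissue.

## Numerical choices and degenerate inputs

* Standardization uses the population sd; zero-variance genes become
  all-zero columns with a warning, and a single-sample matrix is an error.
* Overlap filtering measures sharing as $|A \cap B| / \min(|A|,|B|)$
  (flags nested sets; Jaccard available) and removes greedily: most
  violating partners first, ties to the larger set, then the
  lexicographically later id — deterministic and near-minimal.
* "More than 10 genes" is strict (keep ≥ 11); the upper bound keeps ≤ 30.
* Spearman ties: average ranks. All-zero weight columns give zero marginal
  relevances with a warning. `top_genes` breaks |weight| ties
  lexicographically.
* Sign canonicalization (flip each column so its largest-|weight| gene is
  positive, decoder compensated — exact for odd activations) is available
  but off by default; no diagnostic needs it, since all robustness
  measures use absolute correlations.
* Model bundles are HDF5 with float64 payloads; save → load → score is
  bitwise identical, and corrupted or version-mismatched bundles are
  rejected.

## Problem sizes

Test and acceptance fixtures use 100–500 samples and 3–23 gene sets of
8–25 genes. The robustness comparison trains 4 initializations under each
of three schedules; the pruning experiment trains 6. At these sizes the
numpy implementation trains a full model in a few seconds on one CPU; the
whole acceptance script completes in about a minute.

## Limitations

* No GPU path and no minibatch parallelism; very large collections
  (thousands of sets on tens of thousands of genes) will train slowly.
* Raw-count preprocessing (VST, batch correction, probe mapping) is
  upstream by design.
* The score sign is arbitrary; downstream analyses should either use the
  provided canonicalization or, like the diagnostics here, work with
  absolute correlations.
* Transfer-learning workflows (fine-tuning a trained model on a new
  dataset, growing the bottleneck with new sets) are not implemented.
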