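# Methods

## Problem and data model

The package classifies 41-nt DNA windows centered on a putative
modification site into five classes: N4-methylcytosine (4mC),
5-methylcytosine (5mC), 5-hydroxymethylcytosine (5hmC),
N6-methyladenine (6mA), and unmodified adenine windows (6mA-neg).  The
central base (0-based index 20) is an A for the adenine classes and a C
for the cytosine classes; a `[CLS]` classification token is prepended
before modeling, so the model always sees token sequences of length 42
with the site at token index 21.  Windows are assumed pre-extracted;
strings are taken as given (no reverse-complement handling).

Redundancy filtering is greedy, single-pass and order-preserving: a
window is dropped if its ungapped per-position identity to any earlier
kept window is ≥ 0.80 (inclusive).  Because all windows share one
length, exact column matching replaces alignment; the word-filter
heuristics of general-purpose clustering tools add nothing at 41 nt.

## Classifier

Pipeline: token embedding (default width 256) → kernel-3, stride-1,
zero-padded 1-D convolution (k-mer aggregation) → five residual blocks
→ two multi-head self-attention blocks → `[CLS]`-row pooling → fully
connected softmax head.  Every stage preserves the sequence length of
42, which keeps attributions alignable to input positions.

Choices where the architecture is otherwise underdetermined:

* **Residual block.** `y = F(x) + x` with `F` = two
  (convolution → layer normalization → ReLU) stages, window 3,
  channels preserved; a 1-window projection shortcut `W_s x` handles
  channel changes.  Layer (not batch) normalization is used for
  batch-size independence.
* **Attention.** Per head `softmax(QKᵀ/√d_k)V`; heads concatenated and
  projected by `W^O`.  Default 8 heads (d_k = 32 at width 256).  No
  residual path or feed-forward sublayer is wrapped around attention;
  the blocks are plain multi-head self-attention.
* **Positional information.** No positional encoding is added; local
  order enters through the convolutions and classification is content
  based.  A consequence worth knowing: the model cannot distinguish a
  motif by its absolute offset, only by its presence.
* **Pooling.** The `[CLS]` row feeds the head; mean pooling is
  available via `ModelConfig(pool="mean")`.
* **Dropout.** 0.1 after each attention block during training.

The compute core is a small tape-based reverse-mode autodiff engine
over float64 NumPy arrays (`dnamod.tensor`), providing exactly the
operations the model needs.  Gradients are verified against central
finite differences in the test suite; the same machinery yields the
exact input gradients required by integrated gradients.

## Training

Focal loss `FL(p_t) = -α_t (1-p_t)^γ log(p_t)` with γ = 2 and α set to
inverse class frequency normalized to mean 1 (both configurable);
cross-entropy is the γ = 0, α = 1 special case and is exposed as
`cross_entropy_params()`.  p_t is clipped to [1e-12, 1-1e-12] before
the logarithm.  Optimization is Adam (default 1e-3, batch 64, up to 50
epochs) on a stratified 80/20 train/validation split, all reproducible
from one seed.

Early stopping monitors **validation accuracy** by default (patience
5), restoring the best parameters under the monitored quantity;
`monitor="val_loss"` is available.  The accuracy monitor is a
deliberate choice: with strong inverse-frequency α and a minority
validation fold of a few dozen samples, the focal validation loss is
dominated by a handful of confidently misclassified minority samples —
on the default synthetic conditions it reaches its minimum around
epoch 5 and then rises while validation accuracy still climbs from
~0.85 to ~0.91, so loss-based restoration systematically returns
under-trained models.

## Synthetic data generator

Each class draws window bases i.i.d. from a background composition
(default uniform), plants a class-specific motif starting 2 nt
downstream of the site (offset 22) with per-position fidelity 0.95,
then forces the central base to the class chemistry.  6mA-neg carries
no motif.  Default counts are 500 per class with 5hmC at 50 (10%),
which makes the focal-loss comparison meaningful.  The default motifs
are 6-mers echoing reported methylation-context motifs (ATTTCC for
4mC, CCGTAA for 5hmC, CCTCAG for 5mC, CGAGAA for 6mA).

What the generator does *not* emulate: real genomic k-mer statistics,
CpG context, species structure, positional jitter of motifs, or
correlated flanking composition.  Passing the end-to-end tests shows
the pipeline recovers planted signal under controlled conditions; it
says nothing about accuracy on real multi-species data.

With a 6-mer planted at offset 22, positions 22–25 of the motif fall
inside the site ± 5 attribution segment and positions 26–27 fall
outside it; motif-recovery checks therefore score the segment-visible
positions, while the masking experiment uses the full span.

## Interpretation suite

* **Integrated gradients.** Zero-embedding baseline, target = the
  true-class logit, right-endpoint Riemann accumulation at k/steps,
  k = 1..50.  Per-token attribution is the *sum* over embedding
  dimensions of elementwise (input − baseline) × average gradient, so
  the completeness axiom holds at token level; the residual
  Σ attributions − (F(x) − F(0)) is recorded per track.  Residuals
  shrink with step count but convergence is slowed by the layer-norm
  singularity at the zero baseline — completeness checks are therefore
  phrased relative to the logit gap of a trained model.
* **Sample selection.** True-class probability strictly > 0.3.
* **Segments.** One site-centered segment per sequence, site ± 5
  (11 bases, 10 flanking units).
* **Clustering.** Segments one-hot encoded (44-dim), embedded to 2-D
  by UMAP (15 neighbors, fixed seed), grouped by DBSCAN with
  min_samples = minimum cluster size (10); ε defaults to the elbow of
  the sorted k-distance curve (maximum deviation from its chord).
  Noise points are excluded; clusters are reported largest first.  If
  all segments are identical the manifold step is skipped and a single
  cluster returned.
* **PWMs.** Per-position base frequencies with a 0.01 pseudocount per
  base, renormalized; exported in MEME minimal format for downstream
  comparison (e.g. TOMTOM).  Motif significance calls are delegated to
  those external tools.
* **Masking.** Tokens are replaced by the `[CLS]` id.  Inside mode
  masks within the motif span but never the site; outside mode masks
  anywhere else but never the leading `[CLS]` token.  At least 10
  repetitions; mean and standard deviation of class recall reported.
* **Correlation.** Per class, the `[CLS]` row of the last hidden layer
  is averaged over records; the 5×5 matrix is the Pearson correlation
  of those means (Spearman behind a flag).

## Problem sizes for the reproduction runs

The acceptance script and the heavy tests run the reduced
configuration (embedding 32, two residual blocks, one attention block,
8 heads) on the default dataset (2,050 windows), training up to 60
epochs at learning rate 3e-3 with patience 10; motif discovery uses a
120-per-class subsample; the focal-versus-cross-entropy comparison
uses a half-scale dataset (250 per class, 25 minority) with a fixed
10-epoch budget over 5 matched seeds.  These sizes are the package's
own desk-scale choices for the synthetic study.

## Known limitations

* Training the full-width model (embedding 256, five residual blocks)
  is functional but slow on CPU; the reduced configuration is the
  practical default for experimentation.
* DBSCAN's ε heuristic can fragment a class into several clusters on
  weakly separated segment populations; only the largest cluster per
  class is used for motif recovery.
* Attribution and masking analyses assume the motif span is known (for
  synthetic data) or supplied; no de-novo span inference is done.
* The 0/0 → 0 metric convention deliberately under-reports performance
  for degenerate folds rather than failing.
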