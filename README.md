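# dnamod

Multi-class prediction of DNA methylation modifications from sequence,
with attribution-based motif discovery.

DNA bases carry several chemically distinct methylation marks —
N4-methylcytosine (4mC), 5-methylcytosine (5mC),
5-hydroxymethylcytosine (5hmC) and N6-methyladenine (6mA) — and
distinguishing *which* modification sits at a site, rather than just
whether one does, is a 5-class problem (the fifth class being
unmodified adenine windows, 6mA-neg).  `dnamod` is for computational
epigenetics researchers who want a transparent, dependency-light
implementation of this task: a residual-convolution + self-attention
classifier over 41-nt windows, focal-loss training for the heavily
under-represented 5hmC class, and an interpretation suite that turns
the trained model's integrated gradients into position weight
matrices.

## Model

A window `x₁…x₄₁` with the modified base at position 21 (1-based) is
prepended with a `[CLS]` token and embedded (default 256-dim per
token).  The representation then passes through

1. a kernel-3 1-D convolution (k-mer aggregation),
2. five residual blocks `y = F(x) + x`, `F` = 2 × (conv → layer norm →
   ReLU), all length-preserving (sequence axis stays 42 throughout),
3. two multi-head self-attention blocks,
   `Attention(Q,K,V) = softmax(QKᵀ/√d_k)V` per head, heads
   concatenated and projected by `W^O`,
4. a softmax head over the `[CLS]` row.

Training minimizes focal loss `FL(p_t) = -α_t (1-p_t)^γ log p_t`
(γ = 2, α = inverse class frequency), which down-weights easy examples
and rescues minority-class recall.  Interpretation computes integrated
gradients of the true-class logit from a zero-embedding baseline (50
path points), keeps samples with true-class probability > 0.3, extracts
site ± 5 segments, clusters them (UMAP + DBSCAN) and summarizes each
cluster as an 11 × 4 PWM exportable in MEME minimal format.  A masking
experiment (`[CLS]` as the mask token, ≥ 10 repetitions) quantifies how
much motif-internal vs. motif-external positions support recall, and a
5 × 5 Pearson matrix correlates the per-class mean hidden
representations.

Everything runs on a small built-in NumPy autodiff core — no deep
learning framework required.  Gradients are verified against finite
differences in the test suite.

## Worked example

Train a reduced-size model on the bundled synthetic generator (500
windows per class, 5hmC deliberately at 50, a class-specific 6-mer
planted next to the site with 95% fidelity) and evaluate on a fresh
draw:

```python
from dnamod import (
    SyntheticSpec, generate_dataset, MethylationClassifier, ModelConfig,
    TrainConfig, train, evaluate_predictions,
)
from dnamod.records import encode_dataset

spec = SyntheticSpec(seed=7)
data = generate_dataset(spec)
model = MethylationClassifier(ModelConfig(
    embed_dim=32, n_resnet_blocks=2, n_attention_blocks=1, n_heads=8, seed=1))
history = train(model, data, TrainConfig(epochs=60, learning_rate=3e-3,
                                         patience=10, seed=1))

test = generate_dataset(SyntheticSpec(
    counts={"4mC": 100, "5hmC": 20, "5mC": 100, "6mA": 100, "6mA-neg": 100},
    seed=1007))
tokens, labels = encode_dataset(test)
report = evaluate_predictions(model.predict_proba(tokens), labels)
print(f"trained {len(history)} epochs; overall accuracy {report.overall_accuracy:.3f}")
print(report.to_frame().round(3))
```

prints

```
trained 27 epochs; overall accuracy 0.881
         accuracy  precision  recall     f1    mcc  roc_auc  pr_auc
4mC         0.971      0.940    0.94  0.940  0.921    0.993   0.978
5hmC        0.986      0.850    0.85  0.850  0.842    0.985   0.920
5mC         0.943      0.858    0.91  0.883  0.846    0.989   0.971
6mA         0.962      0.912    0.93  0.921  0.896    0.993   0.980
6mA-neg     0.900      0.815    0.75  0.781  0.718    0.949   0.866
```

Rows are one-vs-rest per-class metrics (all other classes pooled as
negatives); `overall accuracy` is the plain fraction of correctly
classified windows.  The minority 5hmC class reaches 0.85 recall here
— with plain cross-entropy at the same seeds it typically lands an
order of magnitude lower, which is the point of the focal loss.
Motif discovery then follows with
`dnamod.interpretation.discover_motifs(model, data)`, whose top
cluster per class recovers the planted motif bases.

The same steps are available from the shell:

```bash
dnamod simulate --seed 7 --out data.fasta
dnamod train --data data.fasta --seed 1 --out model.npz
dnamod evaluate --checkpoint model.npz --data test.fasta --out report
dnamod interpret --checkpoint model.npz --data data.fasta --out-dir motifs/
```

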