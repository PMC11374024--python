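# Methods

This note records the model as implemented, the defaults and why, what
the synthetic benchmark does and does not emulate, and the numerical
choices a maintainer would want to know.

## Model

### Ontology algebra

A namespace's terms are kept in one stable order (lexicographic by GO
identifier, 0-based); every matrix, partition, and scatter index uses
it. Ancestry follows `is_a` and `part_of` edges; other OBO relations
(`regulates`, …) are ignored, and cross-namespace edges are dropped at
parse time with a logged count, so each namespace is a self-contained
DAG processed by its own model. The ancestor-closure matrix `A` has
`A[i, j] = 1` iff `i` is an ancestor of `j` or `i = j`; it is
transitively closed and has unit diagonal by construction.

Annotation sets are closed under the true-path rule before training and
evaluation. A propagated pair inherits its evidence code from the most
specific (deepest) originating record; ties break on the stable term
order. Records on unknown or obsolete terms are dropped with a warning
and counted. The default evidence filter keeps the 13 experimentally
grounded codes (EXP, IDA, IPI, IMP, IGI, IEP, TAS, IC, HTP, HDA, HMP,
HGI, HEP); electronic annotations (IEA) are excluded.

`A` is normalized as `Ã = D^{-1/2} A D^{-1/2}` with `D` the diagonal of
row sums. `A` is asymmetric here, and the symmetric-normalization
formula does not dictate a degree notion for that case; row sums reduce
to the standard formula whenever `A` is symmetric, which is why they
were chosen.

### Query processor

Frequency partitioning thresholds are configuration values. Defaults
place boundaries at log-spaced annotation counts — MF/CC: two groups
split at 100 annotations; BP: three groups split at 30 and 100 —
mirroring the rare/common motivation for having experts at all. Within
a group, terms keep the global order, and the scatter index (a
bijection onto `0..Dc−1`) reassembles group outputs into `q`.

Each expert is `depth` (default 2) hidden blocks of
linear → batch norm → GELU with an identity skip, then a plain linear
output layer emitting raw logits. Two reconciliations worth noting:

* a skip connection needs matching widths; when a block changes width
  (e.g. 5120 → 1024 with the reference provider) the skip is omitted
  for that block. Hidden width defaults to `min(1024, D_f)`.
* the output stage emits *raw logits* (the joint head consumes them and
  a logistic maps them to standalone per-group probabilities); a GELU
  at the output would bound logits below at ≈ −0.17, so the last stage
  is linear only.

Sequence features are the mean over per-residue embeddings. Sequences
longer than 1022 residues are split into consecutive 1022-residue
chunks (last chunk shorter), per-chunk embeddings are concatenated
along the sequence before pooling, so the result equals the
residue-count-weighted mean over chunks and is chunking-invariant for
any provider that treats residues independently. Providers are
pluggable: the reference protein language model (dim 5120) is an
external adapter; a deterministic hash-based per-letter provider
(default dim 64) serves development and testing; MSA and domain
annotation providers are declared interfaces only, since they did not
improve the full model in ablation.

Per-group auxiliary supervision — binary cross-entropy on `σ(q)`
against the same labels, weight 1.0, on by default — keeps each expert
predictive on its own group; with the joint head disabled this is
exactly the standalone expert-MLP ablation.

### Label encoder

The text provider for synthetic runs hashes lowercase tokens to seeded
random directions and sums them (normalized by √token-count), so texts
sharing vocabulary get correlated vectors; that is the one property the
downstream encoder needs from a real biomedical text model.

The autoencoder minimizes binary cross-entropy between `σ(Z Zᵀ)` and
`A` over all entries, with the positive class re-weighted by
`#zeros/#ones` (falling back to 1 when either count is zero) — the
standard graph-autoencoder recipe. Optimization is full-batch Adam,
base learning rate 0.01 with cosine decay over the (default 500)
epochs, with per-column standardization of `X` and Glorot-scale
initialization. The decay and standardization matter: constant lr 0.01
oscillates on the badly scaled inner-product logits and plateaus well
short of the separable optimum.

A structural fact to keep in mind when reading reconstruction AUCs: the
inner-product decoder is symmetric while `A` is not, so each directed
ancestor pair ties with its mirrored zero entry. Off-diagonal ROC AUC
is therefore capped at `1 − P/(2N)` (P positive pairs, N negative),
about 0.91–0.94 on the synthetic DAGs used here; observed AUCs ≥ 0.9
are near that ceiling, not far from perfection.

`Z` is frozen after pretraining (the array is made read-only and its
byte hash is checked across joint training). The reference label width
is `D_e = 1024` and the text width `D_t = 768`; the two are distinct
dimensions in this package even though the same symbol is sometimes
used for both elsewhere. One label encoder is trained per namespace.

### Joint head and training

`Dm` (shared embedding width) defaults to 512 at reference scale and 64
in the desk-scale configurations; it is not dictated by the model. The
key/value projections consume rows of `Z`, so their input width is
`D_e`. The output map is the `Dm → Dc` linear map — the only
shape-consistent reading of a residual `o + u` followed by per-term
scores. The raw `q` (not `σ(q)`) feeds the projection `u = Wqᵀq`; the
alternative reading is one flag away (apply the logistic before
projecting) and was not needed.

Training: Adam, lr 1e-3, batch 32, up to 200 epochs, early stopping
with patience 20 on validation loss, best checkpoint restored.
Model selection uses validation *loss*, not Fmax — loss is smooth at
desk-scale validation sizes where Fmax is a step function. Scores are
clipped to `[1e-7, 1 − 1e-7]` inside the loss. Batch normalization uses
batch statistics in training and running statistics in evaluation; a
training batch of size 1 falls back to running statistics to avoid
degenerate normalization.

### Evaluation

Threshold grid: step 0.01 over (0, 1], the CAFA convention; ties on the
optimum resolve to the smallest threshold. Precision at a threshold
averages only over proteins with at least one prediction there (the
CAFA `m(τ)` convention); recall averages over all truth-bearing
proteins. Information content is the marginal surprisal
`−log2(count/n)` in bits (a conditional, parent-given variant would be
a drop-in replacement; the marginal form is the default). Weighted Fmax
replaces TP/FP/FN counts by IC-weighted sums; with uniform IC it equals
Fmax exactly, which is tested. Prediction scores are max-propagated up
the ontology before all metrics so predictions, like truth, respect the
true-path rule. AUPR is the micro-averaged step-wise sum (average
precision, no trapezoids); per-term AUC is the rank-based Mann–Whitney
statistic with mid-ranks for ties; terms with degenerate truth columns
are skipped and reported.

## Synthetic benchmark

The generator emulates: a rooted single-namespace DAG (each non-root
term attaches to 1–`max_parents` earlier terms, ~20% `part_of`);
definition texts embedding each term's own token plus all ancestor
tokens (lineage-correlated vocabulary); leaf prototypes drawn from a
standard normal in feature space; Zipf(1.5) leaf popularity so a rare
stratum (≤10 annotations) exists among 60 terms × 500 proteins; protein
features as the mean of sampled-leaf prototypes plus Gaussian noise
(σ = 0.5 default), mirroring mean-pooled sequence embeddings; evidence
codes drawn uniformly from the 13-code experimental list.

It does **not** emulate: real amino-acid sequences or their
language-model geometry; annotation incompleteness and biased missing
labels; inter-protein homology structure (a leaf-identity holdout
stands in for sequence-identity clustering); multi-namespace proteins;
obsolete-term churn. Passing tests therefore demonstrate that the
architecture, losses, and metrics behave as designed on a recoverable
planted signal — not that reference-scale accuracy transfers to real
proteomes.

Desk-scale problem sizes used throughout (tests and the acceptance
script): 40–60 terms, 80–500 proteins, 64-dim features, label width 64,
`Dm` 64. These keep every stage seconds-fast on one CPU while leaving
all code paths identical to reference scale.

## Known limitations

* The GCN smooths sibling terms toward each other (both Ã
  multiplications), which inflates sibling inner products; together
  with the symmetric decoder this bounds how sharply the closure can be
  reconstructed. Directed decoders (e.g. bilinear with an asymmetric
  form) are out of scope.
* Attention is single-head and single-layer by design; the memory is
  all `Dc` terms, so the softmax is over the full vocabulary and scales
  linearly in `Dc` per protein.
* The numpy training loop is single-threaded and unbatched across
  experts; it is built for clarity and desk-scale reproducibility, not
  throughput.
* Evaluation offers no bootstrap confidence intervals and no
  partial-knowledge protocol; GAF/GPAD qualifiers (NOT, …), GO-slim
  mapping, and taxon constraints are not parsed.
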