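# Methods

## The model

`epimodal` predicts binary epigenetic profiles (transcription-factor
binding, DNase hypersensitivity, histone marks) for genomic windows from
two inputs of very different resolution:

* a **local 1D signal** — the one-hot-encoded DNA of a fixed-length
  window (1 kb by default) centred on a 200-bp bin, sampled on both
  strands (the reverse-complement window is a second sample sharing the
  forward sample's label vector);
* a **global 3D signal** — a whole-genome Hi-C interaction-frequency
  matrix over fixed-resolution bins (100 kb for real data; 5 kb in the
  scaled synthetic fixtures), bridged to the windows by assigning each
  window to the matrix bin containing its centre.

A sequence encoder maps the window to a 925-dimensional embedding:

* `cnn` — three 1D convolutions (320, 480, 960 kernels of width 8) with
  two interspersed max-pools of 4, flattened and affinely mapped to 925;
* `cnn_rnn` — one convolution (320 kernels of width 26), max-pool 13, a
  bidirectional LSTM (320 units per direction), flattened to 925.

A structure encoder maps the window's Hi-C bin to a 128-dimensional
embedding:

* `mlp` — the bin's row of the row-normalised matrix through two hidden
  ReLU layers (256, 256);
* `gcn_topo` — three graph-convolution layers
  `H' = ReLU(Â H W)` over `Â = D^{-1/2}(log1p(A)+I)D^{-1/2}`, starting
  from all-ones node features of width 768 (widths 768 → 256 → 256 → 128);
* `gcn_seq` — the same propagation with node features produced by a
  regional sequence embedder.  The embedder contract is "mean-pooled
  fixed-dimension embedding of the bin's DNA"; the shipped default is a
  deterministic k-mer-composition embedder (per-1-kb k-mer counts,
  mean-pooled, projected by a fixed seeded random matrix).  A pretrained
  DNA language model can be plugged in through the same interface.

The two embeddings are concatenated and fed to one fully connected layer
with `E` sigmoid outputs (919 for the DeepSEA-style label space).  Setting
the structure encoder to `None` gives the sequence-only baseline with the
identical sequence branch, which isolates the contribution of chromatin
structure.  An optional accessibility channel (an affine embedding of the
bin's Hi-C row sum, the 1D ablation input) can be appended; it is off by
default.  A residual-CNN/B-spline sequence-encoder slot is reserved in the
variant enum but not implemented.

## The disparity hypothesis test

Sequence-only predictors are functions of sequence, so window pairs with
similar sequences get similar predictions; yet real profile similarity is
often out of line with sequence similarity.  The test asks whether 3D
proximity explains the mismatch.  Per repeat (three by default) it draws
2% of the samples without replacement, forms all pairs with nonzero
interaction frequency, drops pairs whose profile similarity is undefined
(both profiles empty), converts each pair's sequence similarity
(positional identity, N positions masked) and profile similarity (Jaccard)
to percentile ranks within the drawn pair set, and partitions pairs into

* **under** — sequence percentile lags profile percentile by more than the
  margin (10 points by default),
* **over** — it exceeds by more than the margin,
* **consistent** — otherwise.

One-sided Wilcoxon rank-sum tests then compare interaction frequencies:
"under" vs "consistent" with alternative *greater* (proximity should
explain unexpectedly similar profiles) and "over" vs "consistent" with
alternative *less*.  P-values are exact by enumeration over all
`C(n, n_x)` mid-rank assignments when the combined sample size is at most
12, and otherwise use a normal approximation with tie and continuity
corrections.  Reported output is the per-repeat p-values and the frequency
of p < .05.  Both similarity metrics are strategy options (k-mer cosine
for sequences, cosine for profiles) because the exact published choices
live outside the main text; the defaults here are deterministic and
unit-testable.  Percentiles are computed within each repeat's sample.

## Training

The loss is mean binary cross entropy over all (sample, event) entries
plus L1 and L2 penalties on weights (biases exempt; predictions clipped to
[1e-7, 1-1e-7]).  Optimisation uses Adam (the optimiser is not pinned by
the published description); training runs up to 40 epochs with early
stopping on validation BCE (patience 4 by default) and always returns the
best-validation checkpoint.  Warm starts copy the sequence-encoder
parameters from a pretrained sequence-only checkpoint by name prefix; the
rest of the model starts cold.  Structure embeddings are recomputed per
batch rather than cached per epoch: desk-scale graphs are under 1000 bins,
so the full-graph forward is cheap and end-to-end gradients stay exact.

Evaluation reports per-event AUROC (pair counting with half credit for
ties) and AUPRC (step-wise precision-recall integral, average-precision
convention), macro-averaged over events with both classes present;
degenerate events are listed, not averaged.

## Motif interpretation

For each first-layer kernel (320 in the full-size models; width 8 or 26),
the maximally activating contiguous subsequence of every test window is
located by exhaustive cross-correlation (ties to the smallest offset).
Windows whose maximal activation exceeds 0 contribute their subsequence to
a position-specific frequency matrix with pseudocount 0.001 per cell;
kernels with no qualifying window are reported inactive.  PSFMs are
exported in MEME minimal motif format (version 4, uniform background) for
querying against motif databases with external tools; the query itself is
out of scope.  Reverse-strand windows contribute as stored — they are
separate samples and no orientation collapsing is applied.

## Variant effects

`apply_variant` builds fixed-length reference and alternate windows
centred on the variant's first reference base; for indels the edited
chromosome is re-windowed around the same anchor (the anchoring rule is a
package choice — the published description does not fix one).  Effect
features are the per-event probability differences and log-odds
differences (probabilities clipped at 1e-6 for the logit).

* **Zero-shot**: an aggregation of |Δ probability| is used directly as an
  effect score.  The default is the mean over events; max and L2 modes are
  first-class because the published aggregation is unstated.
* **eQTL**: L2-regularised logistic regression (scikit-learn) on the
  log-odds-difference features, with the encoder held fixed by
  construction.  Cross-validation folds group whole chromosomes (X and Y
  share a fold, greedy count balancing, deterministic per seed); the
  inverse regularisation strength is tuned on held-out chromosomes
  (chr8/chr9 by default), and an optional evaluation-time filter keeps
  variants with |log2 fold change| above a cutoff.
* **Few-shot pathogenicity**: a Siamese classifier — two weight-tied
  copies of the multimodal encoder score the reference and alternate
  windows, the squared differences of the E probabilities feed an E-to-1
  affine + sigmoid head — trained end to end with cross entropy + L2
  (default weight 1e-11, the published tuned optimum; the sweep range
  1e-12…1e-8 is reproduced in the tooling), encoder warm-started and head
  fresh.  The head is initialised at a uniform positive weighting, so the
  untrained classifier ranks variants by the aggregate squared probability
  difference — the natural zero-labelled-data limit — and the untrained
  state competes in early stopping.  With a training size of zero the
  protocol returns the zero-shot scorer.  The output is exactly invariant
  to swapping the inputs.

## Synthetic data

The generator produces, deterministically from (config, seed): a uniform
ACGT genome; one random k-mer motif (8 bp) per event planted into a
fraction of bins (default 0.1) at non-overlapping slots within the bin;
a block-model Hi-C map (round-robin bin communities, intra-rate 10 /
inter-rate 1, power-law distance decay with exponent 1 within chromosomes,
Poisson counts, with an expectation mode for exact unit tests); labels
driven per event either by motif presence in the bin or by the bin's
community (driver drawn with probability β = 0.5 of being structural),
flipped independently at rate ε = 0.05; and variants of which half destroy
a planted motif occurrence by one substitution (effect/pathogenic) and
half are background substitutions outside planted motifs (neutral/benign),
with eQTL signs and log2 fold changes assigned by the generative rule,
never by any model.

What the fixtures emulate — and what they do not: planted motifs are
exact k-mers (no degenerate positions, no positional priors), the contact
map is a clean block model (no TADs, loops, or coverage biases), labels
have independent Bernoulli noise (no correlated assay artefacts), and
label dependence on structure is binary community membership.  Passing the
desk-scale analogues therefore shows that the implementation recovers the
*direction* of the published effects under the assumed generative
mechanism, not that it reproduces genome-scale accuracy numbers.

## Desk-scale benchmark protocols

`epimodal.protocols` freezes the analogue experiments; the test suite and
`scripts/acceptance.py` run exactly these:

* **Profile prediction** (analogue of the sequence-only vs multimodal
  comparison): default fixture (4 × 20-kb chromosomes, 1-kb windows, 5-kb
  Hi-C resolution, 24 events), chromosomes 1–2 for training, 3 for
  validation, 4 for testing; miniature models (single 32-kernel
  convolution with global max pool, embedding width 32; MLP structure
  branch 32-32-16); Adam at 3e-3, up to 25 epochs, patience 4; the
  comparison metric is macro-AUPRC over structure-driven events.
* **Disparity power**: a 6 × 40-kb fixture.  The test draws only 2% of
  samples (the published sampling rate, kept as-is), so this experiment
  uses a larger genome than model training does — power comes from pair
  count, and training cost is irrelevant here.
* **Variant scoring**: a 4 × 100-kb fixture with 400-bp windows and 900
  variants.  Short windows and longer chromosomes trade flank length for
  window count, because learning exact planted k-mers from scratch needs
  a few thousand windows; pretraining runs the full 60 epochs (patience
  disabled) since motif discovery by gradient descent passes through a
  long plateau that validation-loss early stopping would mistake for
  convergence (the best-validation checkpoint is still what is kept).
  400 variants train the Siamese classifier, 100 validate it, and the
  rest (≈400) are the test set, mirroring the published 0→400-variant
  protocol at its largest size.

A note on miniature depth: the full-size three-convolution stack is kept
verbatim for architecture contracts, but at a few thousand training
windows it memorises before its first-layer kernels align with any
motif — a sample-complexity effect, not a defect of the layout, which was
designed for millions of windows.  The miniature sequence encoder is
therefore a single convolution with a global max pool (`final_pool = 0`),
the shallowest member of the same family, which learns planted motifs
reliably at this scale.  The `final_pool` constant is 1 (identity) in the
full-size configuration.

## Numerical choices and degenerate inputs

* One-hot N handling: all-zero columns; windows with more than 10% N are
  excluded from training sets (configurable).
* Contact ingestion symmetrises by elementwise max, tolerating
  upper-triangle-only files; zero rows stay zero under row normalisation
  and contribute only their self-loop under the symmetric scheme.
* Rank-sum ties use mid-ranks; exact enumeration below a combined size of
  12, otherwise tie-corrected normal approximation with continuity
  correction.
* Empty partition cells record NaN for that comparison rather than
  raising; constant similarity vectors report Spearman rho as NaN.
* AUPRC/AUROC require both classes; degenerate events are excluded from
  macro means and reported.
* All randomness flows from integer seeds through `numpy` generators; the
  CLI exposes one `--seed` per subcommand.

## Known limitations

* The published genome-scale results (AUPRC ≈ 0.34–0.42 on 919 events,
  zero-shot AUROC ≈ 0.75) require the full ENCODE/Roadmap training data,
  real Hi-C, and GPU-scale training and are out of reach of this package's
  desk-scale harness; the analogues above check directions of effect.
* The numpy autodiff core is single-threaded BLAS-bound and intended for
  miniature models; it is not a general deep-learning runtime.
* The regional k-mer embedder captures composition only, not context; it
  stands behind the language-model interface, not in for its quality.
* Real multi-resolution Hi-C container formats (e.g. cooler files) are
  not read directly; contacts enter as dense or COO text at one
  resolution.
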