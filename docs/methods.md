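# Methods

## Problem and model

Nucleic acid nanoparticles (NANPs) are defined assemblies of short DNA
and RNA strands — four-stranded triangles, five-stranded squares,
six-stranded pentagons (planar), and six-stranded cubes (globular).
Their innate-immune footprint in human microglia is summarized by two
secreted cytokines, IFN-β and IL-6 (pg/mL), which this package models
on the log10 scale as a function of the strand sequences alone
(a sequence-based QSAR).

The primary regressor is a small transformer encoder:

1. each strand is tokenized into overlapping k-mers (k = 3; a strand of
   length L contributes L − k + 1 tokens);
2. the strands of a construct are concatenated with an explicit `SEP`
   token (k-mer windows never span strand boundaries — a spanning
   window would fabricate junction motifs that do not exist
   chemically), right-padded with `PAD` (index 0) to a fixed length;
3. token embeddings plus learned positional embeddings feed
   `num_blocks` post-norm transformer blocks (multi-head self-attention
   with PAD keys masked, position-wise feed-forward, residual + layer
   norm), then a global average pool over non-PAD positions and a
   single linear output.

Because a flat token stream does not represent inter-strand
connectivity, the training set is augmented with systematic strand
permutations: each construct contributes min(n!, cap) orderings
(identity first; beyond the cap, orderings are sampled uniformly
without replacement, seeded).  The model trained this way
(`transformer_m1`) is compared against the same architecture trained
on identity orderings only (`transformer_noaug`, cap = 1), an LSTM
encoder over the same token streams, and a Random Forest on
order-invariant composition descriptors (RNA-base ratio, strand count,
total length, GC and purine fractions, mononucleotide frequencies).
One single-output model is trained per endpoint.

DNA and RNA share one vocabulary with `T` and `U` as distinct symbols,
so strand chemistry is readable from the tokens themselves.

## Training

Adam minimizes the mean absolute error of log10 predictions.  Early
stopping monitors a group-aware validation slice (all permutation
variants of a construct stay on one side); the best-validation-epoch
weights are restored.  The trainer additionally supports, and the
reduced validation schedule uses:

* decoupled (AdamW-style) weight decay;
* Polyak/EMA weight averaging (validation and the final model use the
  averaged weights);
* reduce-on-plateau halving of the learning rate;
* token dropout — a random fraction of input tokens is PAD-masked per
  step.  The response depends on sequence composition, which survives
  token subsampling, while memorized record-specific patterns do not;
  on 150-record training sets this is the single most effective
  regularizer.

Default architecture/training values (`TransformerConfig`): embedding
64, 2 blocks, 4 heads, feed-forward 128, dropout 0.1, learning rate
1e-3, ≤200 epochs, batch 32, patience 20.  The published work does not
disclose its hyperparameter table, so these are conservative
small-data defaults; every value is overridable from the CLI config.

At inference a prediction is the mean over min(n!, 24) strand-ordering
encodings (identity included); the standard deviation across orderings
is reported as the permutation spread.  Descriptor models are
order-invariant and report spread 0.

## Evaluation protocol

The panel is split 70/30 (stratified by shape, seeded; |train| =
⌊0.7 n⌋, so 176 constructs give 123/53).  On the training side, 5-fold
cross-validation repeated 10 times partitions parent records — never
augmented variants; augmentation is applied inside each training fold
only, and a fold-level assertion verifies that no variant of a
validation record reaches training (group integrity).  R² (Eq. form
1 − Σ(ŷᵢ−yᵢ)²/Σ(yᵢ−ȳ)²) and RMSE are computed on the log10 scale.
The best fold model (minimal RMSE; ties by higher R², then lowest
(repeat, fold)) is evaluated once on the untouched external test set;
a fingerprint check refuses evaluation on any record seen in training.
Model families are compared with the Friedman rank test over the 50
repeat × fold cells, χ²_F = 12n/(m(m+1)) · Σⱼ(R̄ⱼ − (m+1)/2)², with
average ranks on ties and the asymptotic χ²(m−1) p-value.  The
statistic is computed from this closed form (rather than a library
call) because tie-corrected variants return NaN on fully tied
matrices, where the untied statistic is 0; a library implementation
serves as a cross-check on tie-free matrices in the tests.

## Melting curves

Thermal denaturation is treated as a cooperative two-state transition:
absorbance follows the Boltzmann sigmoid
F(T) = A1 + (A2 − A1)/(1 + exp((Tm − T)/w)), so F(Tm) = (A1+A2)/2 and
w sets the slope at Tm.  The sign convention makes w > 0 an increasing
(hyperchromic) melt; hypochromic traces are handled by A2 < A1.
Fitting uses bounded least squares with A1/A2 initialized from the
low-/high-temperature ends, Tm from the half-amplitude crossing, and
w = (temperature range)/10; Tm is constrained to the measured range.
Flat traces and non-convergence are reported with `converged=False`
diagnostics rather than exceptions.  Constructs with two thermal
transitions (triangles show this) are outside the single-sigmoid model
and surface as elevated residual RMSE.

## Synthetic library generator

The generator emulates the 176-construct panel (16 triangles, 32
squares, 64 pentagons, 64 cubes) with strand lengths 20–30 nt and, per
shape, a ladder of RNA/DNA strand mixtures spanning RNA-base ratio
0 → 1.  Ground truth is log-linear:

    log10 y = intercept + β_rna · ratio + β_3D · [cube]
              + β_motif · [motif present] + ε,   ε ~ N(0, σ)

with defaults σ = 0.05 and (intercept, β_rna, β_3D, β_motif) =
(1.55, 1.10, 0.22, 0.12) for IFN-β and (2.25, 0.95, 0.28, 0.12) for
IL-6.  These are calibrated — and checked at generation time — so that
all-RNA cubes land in the empirical 3D envelopes (IFN-β 750–1000,
IL-6 3000–8000 pg/mL) while 2D constructs stay below 750 and
2500 pg/mL, and DNA-rich constructs are near-quiescent.

Two sequence-level mechanisms make the non-composition terms readable
from tokens, standing in for features of real designs:

* a deterministic 12-nt shape tag opens strand 1 of every construct
  (real shape families share long scaffold stretches).  Tags are drawn
  over {A,C,G} (valid in DNA and RNA) with pairwise-disjoint 3-mer
  sets; an earlier 6-nt design shared 3-mers between pentagon and cube
  tags and left the 3D effect essentially unlearnable against the
  random background;
* the immunostimulatory motif is a planted trimer (`CAC`): background
  occurrences are rejected during strand generation and the trimer is
  inserted into a seeded 50% of constructs, so presence is a clean
  binary signal rather than a near-certain random event.

True coefficients and motif flags are written to the dataset metadata
(`truth.json`) and are exactly recoverable from a noiseless library by
ordinary least squares.

What the generator does **not** emulate: real thermodynamic assembly,
secondary structure, inter-strand complementarity, assay
heteroscedasticity beyond the log-normal term, or batch effects.
Passing the synthetic recovery tests therefore shows that the
pipeline — tokenization, augmentation, training, leakage-guarded
evaluation — recovers sequence-encoded signals of realistic magnitude
under realistic noise; it does not certify performance on laboratory
panels.

## The reduced validation experiment

Routine validation (the test suite and `scripts/acceptance.py`) runs a
reduced problem size chosen by this package: a 150-construct training
library (14/28/54/54 per shape) and a 53-construct external test
library; transformer with embedding 32, 1 block, 4 heads, feed-forward
64, token dropout 0.3, weight decay 0.1, EMA 0.995, learning rate
3e-3, ≤100 epochs (patience 15), augmentation cap 6, batch 64.  The
trained regressor is a 2-seed-replicate prediction-averaging ensemble
(members differ only in initialization/shuffling seed), and the
early-stopping epoch is selected on permutation-augmented validation
variants (cap-matched), which is a far less noisy model-selection
signal than a single ordering.  Under these conditions the augmented
transformer reaches held-out R² ≈ 0.85–0.93 across library-draw
seeds.  For scale: a ridge regression on raw 3-mer counts — a strong
linear baseline with oracle-free access to the same information —
reaches ≈ 0.84–0.88 on the same draws, so the 150-record noisy
training set places this task near its estimation-variance frontier.

Two controls accompany it:

* **Shuffled labels.**  Training labels are permuted across records.
  A plain random permutation retains chance correlation
  ~N(0, 1/√(n−1)) with the signal directions, which a regressor
  exploits; the permutation is therefore drawn subject to
  |corr| ≤ 0.02 against the true labels and each signal direction
  (ratio, 3D indicator, motif flag), instantiating the null exactly.
  Because R² estimated on 53 records carries ~±0.08 sampling noise
  from test-side chance correlation alone, the control's skill is
  estimated on a 20×-enlarged held-out panel (1060 records); there,
  R² > 0.1 would require genuine learned signal.  The transformer's
  own R² is still measured on the 53-record test set.
* **Permutation invariance.**  The median (over test constructs)
  standard deviation of predictions across 24 strand orderings is
  compared between the augmented model and the cap = 1 model;
  augmented training yields the smaller spread — the
  topological-invariance property that motivates the augmentation.

## Numerical choices and degenerate inputs

* log10 of a zero cytokine reading uses a 0.1 pg/mL clamp (recorded in
  metadata; invertible above the floor).  Negative readings are hard
  errors.
* Sequences are upper-cased and whitespace-stripped; any character
  outside {A,C,G,U,T}, or U and T in one strand, is a hard error (no
  IUPAC ambiguity codes — none occur in these constructs).
* Encodings longer than `max_len` (fixed at vocabulary build time as
  the longest encoded variant rounded up to a multiple of 8) raise by
  default; truncation is opt-in and logged.
* An all-PAD input is pooled with a guarded denominator and returns a
  finite value.
* The neural models run on a compact tape-based reverse-mode autodiff
  engine over numpy (float32); its gradients are verified against
  central finite differences in the test suite.  Determinism: every
  RNG (initialization, shuffling, dropout, permutation sampling,
  generator) is seeded, so fixed seeds reproduce runs bit-identically
  on the same BLAS configuration.

## Known limitations

* Pentagon and cube share a strand count, so on real panels the 2D/3D
  distinction must be learnable from actual sequence families; the
  generator's shape tags are an idealization of that.
* The single-sigmoid melting model under-fits two-transition traces.
* The Friedman comparison uses the asymptotic χ² distribution; exact
  small-sample tables are not implemented.
* Augmentation caps beyond 6! = 720 never occur for this panel's
  architectures; larger assemblies rely on seeded subsampling.
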