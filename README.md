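# nanpqsar

Sequence-based QSAR modeling of the innate-immune footprint of nucleic
acid nanoparticles (NANPs).

NANPs are designed assemblies of short DNA/RNA strands — planar
triangles (4 strands), squares (5), pentagons (6), and globular cubes
(6) — whose immunostimulatory profile in human microglia is summarized
by secreted IFN-β and IL-6 (pg/mL).  Measuring those cytokines takes
days per construct; this package predicts them directly from the
strand sequences, for nanotechnologists screening candidate designs
before committing to assembly and cell work.

## The model

Targets are modeled on the log10 scale, y = log₁₀(pg/mL).  Each strand
is tokenized into overlapping 3-mers; a construct's strands are joined
with a `SEP` token and fed to a transformer encoder — token + learned
positional embeddings, multi-head self-attention blocks, global
average pooling over non-PAD positions, and a scalar regression head —
trained with Adam on a mean-absolute-error loss.  Because a flat token
stream cannot represent which strand ordering is "canonical", training
is augmented with systematic strand permutations (all n! orderings up
to a cap of 720); the resulting model, `transformer_m1`, learns
effectively order-invariant features.  Comparators: the same
architecture without augmentation, an LSTM, and a Random Forest on
composition descriptors (RNA-base ratio = fraction of bases on RNA
strands, strand count, length, GC/purine content).

Evaluation follows a fixed protocol: a stratified 70/30 split, 5-fold
cross-validation repeated 10 times over *parent constructs* (every
permutation variant stays in its record's fold — a leakage guard),
selection of the best fold model by RMSE (ties by R²), one evaluation
on the external test set, and a Friedman rank test,
χ²_F = 12n/(m(m+1)) · Σⱼ(R̄ⱼ − (m+1)/2)², to compare model families
across the 50 fold cells.

UV-melting curves are fitted with the Boltzmann sigmoid
F(T) = A1 + (A2 − A1)/(1 + exp((Tm − T)/w)) to report each construct's
melting temperature Tm.

A bundled synthetic generator emulates the 176-construct study panel
(16/32/64/64 per shape, RNA/DNA mixture ladders, log-linear response
with multiplicative noise, calibrated to the empirical cytokine
envelopes) so the whole pipeline is testable without any external
data; see `docs/methods.md` for the model, assumptions, and what the
synthetic results do and do not show.

## Worked example

```python
import numpy as np
from nanpqsar import (GeneratorParams, generate_library,
                      log10_transform_targets, split_dataset,
                      make_rf_factory, repeated_group_cv, select_best,
                      external_evaluate, IFNB,
                      generate_melting_curve, fit_boltzmann)

lib = log10_transform_targets(generate_library(GeneratorParams(seed=7)))
train, test = split_dataset(lib, train_fraction=0.7, seed=7)

summary = repeated_group_cv(train, make_rf_factory(n_estimators=200),
                            IFNB, k=5, repeats=10, seed=7)
best = select_best(summary)
r2, rmse, _ = external_evaluate(best, test, IFNB)

fit = fit_boltzmann(generate_melting_curve(
    0.2, 0.9, 62.0, 4.0, noise_sd=0.007, rng=np.random.default_rng(1)))
```

prints (via the accompanying report lines):

```
panel: 176 constructs -> 123 train / 53 test
5x10 CV (descriptor RF, IFN-beta): R2 = 0.823 +/- 0.050, RMSE = 0.157 +/- 0.017 (50 folds)
external test: R2 = 0.769, RMSE = 0.149 (log10 pg/mL)
Boltzmann fit: Tm = 62.03 C, w = 3.98 C, converged = True
```

The descriptor Random Forest reads the composition signal (R² ≈ 0.8)
but not the sequence-encoded shape and motif effects; the augmented
transformer, trained the same way, reaches held-out R² ≈ 0.9 on the
same synthetic conditions (that run takes a few minutes; see
`scripts/acceptance.py`).  The Boltzmann fit recovers the planted
Tm = 62 °C from a 1%-noise melting trace.

## Command line

```
nanpqsar simulate --seed 3 --out sim/              # synthetic panel (manifest, endpoints, truth)
nanpqsar train    --manifest sim/manifest.csv --endpoints sim/endpoints.csv \
                  --endpoint ifnb --model transformer_m1 --out run/
nanpqsar predict  --manifest new_designs.csv --model-dir run/model --out preds/
nanpqsar evaluate --manifest ext.csv --endpoints ext.csv --model-dir run/model --out eval/
nanpqsar fit-melt --curves melting.csv --out fits/
```

Every command writes a `run_config.json` snapshot (resolved options and
seeds) sufficient to reproduce its outputs.  Strand manifests are CSV
(`nanp_id,shape,strand_index,strand_id,nucleic_type,sequence`, with
`nucleic_type=auto` inferred from U/T) or FASTA with
`>nanp_id/strand_index` headers; endpoints are
`nanp_id,ifn_beta_pg_ml,il6_pg_ml`.

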