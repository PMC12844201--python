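# omigrow

Growth-associated feature discovery from paired transcriptomic and
proteomic profiles.

## The problem

When a bacterium such as *Rhodopseudomonas palustris* is grown on a
panel of lignin breakdown products — monolignols, acid derivatives,
kraft lignin — under aerobic and anaerobic regimes, which genes and
proteins actually set the growth rate? Classical differential
expression looks at one feature at a time and misses joint, non-linear
effects. The alternative reconstructed here: train regressors that map
each condition's omics profile to its measured growth rate, then ask
every feature how much the model's predictions degrade when that
feature's values are shuffled across conditions.

omigrow implements that workflow end to end as a library, for
computational biologists who want to apply it, stress-test it, or
understand its failure modes on data where the right answer is known.

## The method

Given a conditions × features matrix X (one per omics layer,
standardized per feature to zero mean and unit variance) and growth
rates y (1/h) fitted per condition from OD660 curves with the logistic
model OD(t) = K/(1 + ((K−OD0)/OD0)e^(−rt)):

1. **Fit** three regressor families on the full dataset — a deep MLP
   (12 × 200, 1000 iterations, seed 42), a random forest (1000 trees)
   and an RBF-kernel SVR (C = 100, ε = 0.01) — and benchmark them by
   MAE, MSE and accuracy = 100·(1 − mean |ŷ−y|/y).
2. **Rank** features by permutation importance: the mean MSE increase
   over 30 seeded shuffles of each feature's column,

       Δⱼ = E_π[ L(y, f(X with column j permuted by π)) ] − L(y, f(X)).

3. **Combine** the two layers: min–max normalize each layer's Δ over
   the locus-matched features and sum, giving a combined score in
   [0, 2] per gene/protein pair; take the top 20.
4. **Retrain** on a reduced panel (e.g. eight transport proteins) and
   compare accuracy against the full model.
5. **Test** the selected proteins for aerobic vs anaerobic abundance
   differences (Welch's t-test, Benjamini–Hochberg FDR) and rank them
   by coefficient of variation (sd/mean).

Because the method's original measurements are not publicly deposited,
the package ships a first-class synthetic-data generator that plants a
known driver set: eight co-regulated proteins whose abundances
deterministically set the growth rate through a saturating uptake law,
embedded in a co-expression-structured background, with tunable
transcript–protein coupling and growth noise. Every downstream stage is
validated against this planted truth. See `docs/methods.md` for the
generator's assumptions and for a documented limitation of ANN-based
importance at 14 samples × hundreds of features.

## Worked example

`examples/simulate_and_recover.py` runs the full pipeline on a
simulated study (14 conditions, 200 features per layer, 8 planted
drivers, coupling 0.8, 5% growth noise):

```text
Benchmark (in-sample, training on the full dataset):
          layer family      mae      mse  accuracy_pct
transcriptomics    ANN 0.000273 0.000000     99.867536
transcriptomics     RF 0.007752 0.000082     95.999286
transcriptomics    SVR 0.008833 0.000086     95.504337
     proteomics    ANN 0.000261 0.000000     99.873910
     proteomics     RF 0.006281 0.000057     96.723461
     proteomics    SVR 0.009076 0.000088     95.385579

Recovery of planted truth by combined top-20: 0.375

Reduced-panel comparison (panel = combined top-8):
          layer  n_features_full  panel_size  full_mae  reduced_mae  full_accuracy_pct  reduced_accuracy_pct
     proteomics              200           8    0.0003       0.0003            99.8739               99.8304
transcriptomics              200           8    0.0003       0.0065            99.8675               96.8348
```

What the numbers mean: the over-parameterized ANN nearly interpolates
the 14 training points (accuracy ≈ 99.9%), beating RF and SVR on every
in-sample metric, and an 8-feature panel retains almost all of that
accuracy. The recovery line is the cautionary part: only 3 of the 8
planted drivers made the ANN-based combined top-20 on this seed. The
selection is far above the ~0.10 chance level but incomplete — the
deep network spreads its reliance too diffusely at n ≪ p for
permutation importance to pinpoint every true driver (swap in the
random-forest importance route and all 8 are recovered; see
`docs/methods.md`).

The other examples are single-capability walkthroughs:
`growth_curve_fitting.py` (logistic rate estimation and the
above-control rule), `permutation_importance_basics.py` (Monte-Carlo
vs exhaustive oracle) and `oxygen_differential_analysis.py`
(Welch + FDR + CV ranking).

A thin CLI mirrors the library for shell use:

```bash
omigrow simulate --out data/ --seed 7 --n-features 200
omigrow run --out run1/ --seed 7          # full pipeline on a simulate-spec
omigrow diffstats --matrix data/proteomics.tsv --design data/design.tsv --out diff.tsv
```

All tables are tab-delimited with headers; runs are reproducible byte
for byte from one master seed.

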