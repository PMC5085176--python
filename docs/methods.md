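# Methods

## Problem and model

Carbonylation adds a carbonyl group to K, P, R or T residues under
oxidative stress; for an unannotated protein the question is which of its
many K/P/R/T residues can be carbonylated. `carbonsite` treats each
candidate residue independently through its local sequence context: the
(2ξ+1)-mer window centered on it, padded with the dummy residue X where
the window runs past a terminus. One model is trained per center-residue
type (the *self-consistency principle*): K-centered queries are only ever
scored by the K-trained model, and likewise for P, R, T. Pooling across
residue types is deliberately not supported.

The encoder is a *sequence-coupled* model: every flank position
contributes the probability of the residue observed there given its inner
neighbor (unconditional at positions ±1, whose inner neighbor is always
the center), estimated separately on positive and negative training
windows and differenced. The encoding therefore captures first-order
neighbor coupling along the flank, under the assumptions that (i) the
relevant signal is local to ±ξ residues, and (ii) a first-order chain
directed toward the center is an adequate dependence structure. The
resulting 2ξ-dimensional vector (14-D at the default ξ = 7) feeds a
random forest.

## Benchmark construction

Windows are extracted by sliding over each protein and keeping every
window centered on the configured residue type; annotated centers are
positive, all others negative. Within each subset independently, a greedy
keep-first screen drops any window with pairwise identity ≥ the threshold
(default 0.30) to an already-kept window. Identity between the
fixed-length ungapped windows is a plain column count, with X matching
only X (two windows padded over the same terminus genuinely share that
context), so no external clustering tool is involved; input order is the
tie-break, making the screen deterministic and idempotent.

The 0.30 default is aggressive for 15-mers — any two windows already
share the center, so the floor is 1/15 ≈ 0.07 — which is why both the
threshold and an on/off switch are exposed; the synthetic-data tests run
with the filter off so that generator bookkeeping stays exact.

## Class balancing by Monte Carlo expansion

Positive windows are expanded to the size of the negative subset by
drawing each flank position independently from the positive class's
empirical per-position residue distribution over the 21-symbol alphabet
(20 amino acids in alphabetical order, then X; X is drawn wherever it has
positive probability, as it legitimately appears in padded positives).
Draws are inverse-CDF: a uniform variate r selects the smallest k whose
cumulative probability reaches r, which resolves boundary ties toward the
smaller index. Duplicates among draws are allowed; the profile is fit
once from the original positives and never refit from expanded samples.

Two deliberate tensions are worth stating. The expansion ignores
inter-position coupling even though the encoder models it — synthetic
positives are exchangeable with real ones only up to first-order
marginals. And expanded samples are hypothetical, which is exactly why
the evaluation protocol below quarantines them to training splits.

## Classifier

Encoded windows are classified by a scikit-learn
`RandomForestClassifier`. Hyperparameters are genuinely open (no
principled values attach to this feature set), so the defaults follow
common random-forest practice: 500 trees, √p candidate features per
split, unlimited depth, decision threshold 0.5; all are exposed in
`RFConfig`. A window's score is `predict_proba` for the positive class;
with fully grown trees the leaves are (near-)pure, so this equals the
fraction of trees voting positive. Training and scoring are deterministic
given (data, seed, config).

## Evaluation

Metrics use the N⁺/N⁻/N⁻₊/N₊₋ parameterization (see README), which is
algebraically identical to the standard TP/TN/FP/FN formulas — the test
suite verifies the equivalence to 1e-12 on random counts. When a
predicted class is empty the MCC denominator vanishes; the report then
flags MCC as undefined rather than substituting a number. ROC curves
sweep all distinct scores with ties grouped; the trapezoid AUC equals the
pairwise rank statistic P(score⁺ > score⁻) + ½P(tie), and is
cross-checked against scikit-learn's implementation in tests.

*Target cross-validation* (default K = 10): positives and negatives are
each randomly split into K near-equal folds **before** any expansion; per
round, the training positives are expanded to the training-negative count
(profile fit on original training positives only), the coupling model and
forest are fit on the training split, and only the held-out
experiment-confirmed samples are scored. A hard audit raises on any
synthetic window in a test fold or any site appearing on both sides of a
round. The instruction to substitute the average of the 10 rounds into
the metric formulas is ambiguous between averaging counts and averaging
metrics; the implementation averages the four raw counts over folds and
applies the formulas once (`aggregate`), and also reports the
pooled-count aggregate (`pooled`) and the mean of per-fold metrics
(`mean_fold_metrics`). With near-equal folds the readings differ only in
the third decimal. The jackknife is intentionally not implemented; K-fold
at K = 10 is the supported protocol.

## Synthetic data generator

The generator emulates the *statistical shape* of a carbonylation
benchmark, not its biology: proteins drawn i.i.d. from a background
composition (default uniform over the 20 amino acids), a configurable
fraction of center-residue occurrences designated true sites, and the
flanks of true sites redrawn from per-position distributions in which one
residue per position receives a probability boost (presets: none, weak
+0.15, strong +0.45, on a fixed 14-position motif). Planted sites keep a
minimum separation of 2ξ so no site's motif region is overwritten by a
neighbor's redraw and the planted per-position distributions are exact —
which is what makes parameter recovery (profile ≈ boosted distribution
within binomial error) a meaningful test. Sites may fall within ξ of a
terminus, so padding paths are exercised throughout.

Because the planted signal is exactly per-position categorical
enrichment — the statistic both the positional profile and the coupling
tables estimate — passing tests demonstrate that the machinery recovers
the signal class it models. They do not show that real carbonylation
motifs are of this class, that real backgrounds are i.i.d. uniform, or
how the pipeline behaves under homology-induced redundancy (real
benchmarks need the identity screen precisely because sequences are
related; generated ones are independent).

## Numerical choices

- **Unseen conditioning residue** (α = 0): lookups fall back to the
  position's unconditional distribution (`marginal`, the default) or to 0
  (`zero`); the policy is stored in the serialized model. The marginal
  choice avoids spuriously extreme components for rare contexts.
- **Smoothing** α (additive, over 21 symbols) defaults to 0 — raw
  frequencies — and exists for tiny training sets.
- **Metric boundary cases** are exact by construction (no ε-guards in the
  formulas); fractional counts are accepted so fold-averaged counts can
  re-enter the same formulas.
- **Statistical test calibration**: the Monte Carlo fidelity check
  compares 14 positions × 21 symbols = 294 empirical frequencies to the
  profile. A per-symbol 3-SE band rejects a correct sampler about half
  the time at that multiplicity, so the suite applies the band
  familywise: ≥ 98 % of bands within 3 SE, all within 6 SE. Genuine
  sampler defects (index shifts, bad normalization) produce deviations of
  tens of SEs.
- **Problem sizes**: test corpora range from ~30 proteins (unit level) to
  ~300 proteins / ~2000 candidate sites (end-to-end CV, permutation
  null); the acceptance script uses 120 proteins / ~800 candidates for
  its cross-validation. These sizes put binomial noise well inside the
  asserted bands while keeping the default suite fast on one CPU.

## Known limitations

- Scores are calibrated only in the vote-fraction sense; no probability
  calibration is attempted.
- The encoder's first-order coupling cannot represent longer-range or
  gapped dependencies.
- Published benchmark results for this method family are not
  reproducible from first principles (the underlying curated site lists
  and forest settings are not public); the package's quantitative claims
  are therefore properties — oracle equivalences, permutation nulls,
  parameter recovery, monotonicity in effect size — rather than
  replications of a specific table.
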