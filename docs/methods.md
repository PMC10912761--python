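# Methods

## Model and assumptions

`reopair` treats two-class diagnosis as a problem over within-sample gene
orderings rather than expression magnitudes. The core object is the
relative expression ordering (REO) of a gene pair (i, j) in one sample:
`GREATER` if `x_i > x_j`, `LESS` if `x_i < x_j`, `TIE` on exact equality.
Every downstream quantity — stable-pair sets, reversal pairs, ternary
encodings, predictions — is a function of these orderings only, which
gives the method its defining property: **bit-identical results under any
strictly increasing per-sample transform** of the expression values. This
is what makes signatures transferable across platforms and normalization
pipelines and applicable to a single sample with no reference cohort.

The working assumptions are:

- expression values within one sample are measured on a common monotone
  scale (true of intensities, TPM, FPKM, and their logs);
- a diagnostic signal exists as pairs whose ordering is consistent within
  each class and opposite between classes ("reversal pairs");
- class labels are binary (`case` / `control`), with the case class the
  diseased one (for the motivating application: HCC vs cirrhosis without
  HCC).

## Procedure

1. **Mining.** For a cohort of n samples, pair (i, j) enters the stable
   set when `#{samples with x_i > x_j} / n ≥ θ`. The comparison is
   inclusive ("at least"), ties count toward neither orientation, and
   θ > 0.5 guarantees at most one orientation qualifies. Complexity is
   O(G²·n); the implementation broadcasts one gene row against the whole
   matrix at a time, keeping memory at O(G·n).
2. **Reversal detection** intersects the case-stable set with the
   orientation-swapped control-stable set. Result pairs keep the case
   orientation (gene_i higher in cases).
3. **Whitelist filtering** keeps pairs with BOTH genes in a supplied gene
   set. By default filtering happens after reversal detection (matching
   the discovery order of the motivating study); a `gene_subset` argument
   can restrict mining itself when the full gene space is intractable.
4. **Encoding**: code 0 for `G_i > G_j`, 1 for `G_i < G_j`, −1 for the
   catch-all (absent gene or tie). Encoding one sample never consults
   another sample.
5. **Ranking.**
   - *mRMR*: plug-in discrete mutual information in nats over the three
     code levels; greedy incremental selection, first feature = argmax
     MI(f, T), later steps maximize MI(f, T) minus the mean MI with the
     already-selected set. The set-level criterion this chain optimizes
     excludes self-MI terms from the redundancy sum — a feature's MI with
     itself is its entropy, and counting it would reward degenerate
     constant features. The greedy chain is the canonical practical
     optimizer; it provably matches exhaustive subset search on small
     signal-bearing instances (tested), though not on arbitrary pure-noise
     instances, where no efficient optimizer of the set criterion exists.
   - *MRMD*: `|Pearson r(f, T)| + mean_j cosine_distance(f, f_j)` with
     equal unit weights on the two terms (alternative weights are exposed
     as options). Zero-variance features score relevance 0 with a
     warning; an all-zero code vector contributes cosine distance 0
     rather than aborting the ranking (the standalone `cosine_distance`
     raises on zero vectors, since the quantity is undefined).
   - Ties in both rankers break lexicographically by pair id, making the
     orders fully deterministic.
6. **Incremental feature selection** walks the ranked list, refits the
   classifier on each prefix, and returns the smallest k attaining the
   maximum of the curve. The default evaluation is resubstitution on the
   training samples — the protocol that perfect training-set tables
   imply — with stratified k-fold cross-validation available via
   `cv=k` as the safer alternative; which protocol produced a published
   training table is rarely stated, so both are first-class.
7. **Evaluation**: Sn = TP/(TP+FN), Sp = TN/(TN+FP),
   Acc = (TP+TN)/n, F1 = 2TP/(2TP+FP+FN). AUC is the empirical
   Mann–Whitney concordance with half credit for ties; its 95% CI uses
   DeLong's analytic method (deterministic; validated against R pROC to
   1e−10 on a frozen instance) with a seeded 2000-resample bootstrap as
   an option. Undefined metrics raise `UndefinedMetricError` rather than
   returning NaN; the CLI prints "-" for them, which matters for
   case-only validation cohorts where only sensitivity is defined.

## Classifiers

| kind | backing estimator | fixed settings |
|---|---|---|
| `svm_rbf` | sklearn SVC | RBF kernel, γ = 2, C = 1 |
| `knn` | sklearn KNeighbors | k = 1 by default (the classic IBk default), exposed |
| `decision_tree` | sklearn CART | — |
| `logistic_regression` | sklearn LR | max_iter 1000 |
| `xgboost` | XGBClassifier | 25 rounds, binary:logistic |
| `adaboost_stumps` | sklearn AdaBoost | depth-1 stumps |
| `naive_bayes` | GaussianNB | — |
| `logistic_model_tree` | sklearn LR | stand-in approximation |

`decision_tree` and `logistic_model_tree` are standard CART / logistic
stand-ins for the Weka J48 and LMT learners sometimes used in this
field; they are not bit-compatible with those implementations and no
equivalence is claimed. All stochastic estimators take an explicit seed
(package default 20240304); fits are reproducible bit-exactly.

## Synthetic cohorts

`generate_cohorts` emulates exactly the structure the pipeline assumes,
not real microarray noise:

- **Background genes** are i.i.d. log-normal per sample (meanlog 5,
  sdlog 1). The marginal shape is irrelevant to every REO quantity —
  only orderings matter — and is chosen to look like linear-scale
  intensities.
- **Planted pairs**: per sample, a Bernoulli draw with probability equal
  to the class's stability parameter decides the pair's orientation; the
  two gene values are then placed as the max/min of two noisy draws
  centred `±delta` (default 0.6 log units) around a pair-specific
  baseline. The orientation is therefore *forced* per sample: at
  stability 1.0 the realized concordance is exactly 1, and in general
  the realized fraction is Binomial(n, stability)/n — converging to the
  stability parameter but fluctuating between cohorts, as it would in
  practice.
- **Baseline spacing** (default 3.0 log units between pairs) keeps
  orderings *between* different planted pairs dominated by the baseline
  gap, hence concordant across classes — cross-pair orderings never
  masquerade as reversal pairs. Keeping `delta` well below the
  background sdlog keeps background genes from sitting stably inside a
  planted gene's class-to-class swing, so background false positives at
  θ = 0.85 are rare (empirically 0 across all seeded checks at
  n = 100/50).

What passing tests on these cohorts shows: the mining/ranking/selection
machinery recovers a planted qualitative signal at the stated stability
and is invariant to monotone distortions. What it does not show:
robustness to correlated biological noise, batch structure, probe-level
artifacts, or class mislabeling — none of which the generator emulates.

Because realized concordance is binomial, recovery of *every* planted
pair in a fixed cohort is itself a random event: at stability 0.95 with
50 control samples, a planted pair clears θ = 0.85 with probability
≈ 0.997, so all 11 clear it with probability ≈ 0.965 per cohort. The
seeded recovery tests use the package's seed convention (20240304 + i)
and document this stochasticity rather than pretending recovery is
certain.

## Numerical choices and degenerate inputs

- MI uses natural log with the 0·ln 0 := 0 convention and clips tiny
  negative rounding error to 0.
- The stability count threshold is `ceil(θ·n − 1e−9)`, making the ≥
  comparison robust to floating-point representation of θ·n (17/20 at
  θ = 0.85 is included, 16/20 is not).
- Exact expression ties encode as −1 and count toward neither ordering
  in mining. How real pipelines resolve ties is generally undocumented;
  this rule is conservative and is applied consistently.
- Greedy mRMR tie-breaks (equal scores within 1e−12) and MRMD
  tie-breaks go to the lexicographically smaller pair id.
- `predict` on a sample whose every signature gene is absent (all codes
  −1) returns a defined label and logs a low-information warning rather
  than failing.
- The train/test splitter assigns `floor(fraction·n)` (≥ 1) samples per
  class-by-stratum cell to training, deterministically from its seed.

## Known limitations

- Mining is O(G²·n) with a Python loop over genes; fine for a few
  thousand genes, but whole-transcriptome mining (≈ 2·10⁸ ordered pairs)
  needs the `gene_subset` restriction or patience.
- The IFS default (resubstitution) is optimistic by construction;
  held-out or cross-validated evaluation should accompany any claim
  about generalization.
- The MRMD weighting of relevance vs distance is fixed 1:1 by default;
  no data-driven weight selection is attempted.
- The packaged 11-pair signature carries no fitted weights; a classifier
  must be trained before it can be applied, and nothing here implies
  clinical validity of the resulting predictions.
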