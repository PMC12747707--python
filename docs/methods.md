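# Methods notes

This note records the scientific and numerical choices behind `fscnlp`:
what the models assume, what the synthetic cohort does and does not
emulate, and the decisions taken where the design was genuinely open.

## The task

Binary classification of first-visit seizure-clinic letters into
*epilepsy* vs *no epilepsy*, using only the anamnesis narrative. The gold
standard is the final diagnosis reached after up to two years of
follow-up; letters whose final diagnosis remains 'unclear' are never part
of the binary task. The initial (first-visit) diagnosis is not a training
label — it stratifies evaluation: Analysis A tests on a random stratified
hold-out, Analysis B on exactly the letters that were initially 'unclear'
but later resolved, the clinically hard cases.

## N-gram Naive Bayes arm

*Preprocessing order matters.* Tokenize → clean → lowercase → n-grams
(max n = 2) → stopword removal. Removing stopwords only after n-gram
generation lets informative stopword-built bigrams survive. Retention is
three explicit mechanisms (a bigram whitelist; negation-first tokens
*geen/niet/nooit/zonder*, English mirror *no/not/never/without*; pronoun +
clinical-noun pairs such as *haar_mond*), because retention is otherwise
known only by example. The Dutch stopword list is frozen as a package data
file; results must not drift with upstream lexicon releases. Numeric
tokens are kept (ages and event frequencies may carry signal); hyphenated
Dutch compounds are kept intact. Both are configurable.

*Weighting and selection.* TF-IDF uses the `count x log10(N/df)`
convention. Pre-ranking keeps the 8000 features with the largest total
TF-IDF mass; recursive feature elimination then drops the least important
10% per round until 300 remain (~31 rounds). Importance is the 5-fold
cross-validated mean of the smoothed NB log-likelihood contrast
`|log P(f|epi) - log P(f|no-epi)|`, multiplied by the feature's overall
occurrence count. The count weighting is essential: the smoothed contrast
of a rare feature is dominated by sampling noise, and with tens of
thousands of candidate bigrams the unweighted (or TF-IDF-mass-weighted)
ranking fills the selected set with rare chance-skewed bigrams. CV folds
are a deterministic function of (document id, label, seed), making
selection invariant to document order. All ties break lexicographically.

*Event model.* The fitted classifier is a multinomial NB with additive
smoothing `alpha` (default grid-tuned over {0.1, 0.5, 1.0, 2.0} by 5-fold
CV). On the selected features the event model consumes **raw counts** by
default, not TF-IDF masses. Rationale: the TF-IDF transform already drives
pre-ranking and RFE, but feeding idf-scaled masses into the likelihood a
second time re-weights each feature's evidence by its idf — rare-bigram
evidence gets inflated and the classifier is no longer consistent with the
count-generative process. Empirically (cohort-scale synthetic corpus,
Bayes bound 0.846 ± 0.008): count event model 0.83, TF-IDF event model
0.74. The weighted variant remains available
(`NBArmConfig(event_weighting="tfidf")`) for sensitivity analysis.
Prediction ties resolve to *no epilepsy* — the clinically conservative
call, since a false positive medicates unnecessarily.

## Sentence-embedding arm

The default provider is an offline mock: each normalized token is hashed
(seeded BLAKE2) to a fixed Gaussian direction in 768 dimensions and a
letter embeds as the sum of its token vectors scaled by `1/sqrt(dim)`.
This preserves token-multiset geometry — cosine similarity grows with
shared vocabulary — and retains length information, so a linear model over
the embedding can represent any linear function of token counts (including
the Bayes log-odds of the synthetic generator). It deliberately has *no*
word-order sensitivity; it is a stand-in that makes the arm testable and
bit-reproducible without a network, not a transformer. The optional
`SentenceTransformerProvider` wraps a pretrained multilingual
Sentence-BERT encoder for use on real text.

Provider-side normalization (exact rules): lowercase; NFKD-fold accented
characters to their base letter; replace non-alphanumerics with spaces;
collapse whitespace.

The classifier is a linear booster: per round, a Newton coordinate update
of the bias and each of the 768 weights on the logistic loss, scaled by
the learning rate and shrunk by the L2 penalty. "Default hyperparameters"
are pinned to `n_rounds=100, learning_rate=0.5, l2_penalty=1.0` for
reproducibility; with enough rounds the fit matches scikit-learn's
L2-regularized logistic regression (cross-checked in the tests to 5e-3).
Decision threshold 0.5, no threshold tuning.

## Evaluation

Metrics are proportions on their own denominators; 95% CIs are exact
binomial (Clopper-Pearson) by default, with Wilson and Wald selectable.
Undefined ratios (zero denominator) are reported as flagged not-a-value,
never silently 0. McNemar's test is computed with and without continuity
correction (`(|b-c|-1)^2/(b+c)` vs `(b-c)^2/(b+c)`, df = 1; no discordant
pairs → statistic 0, p = 1). The `ConfusionMatrix.n_total` override exists
solely to reproduce published denominators that their four cells do not
sum to.

Short letters (< 20 words by default) are excluded *before* splitting.
The threshold sits below the calibrated generator's length floor (63
words), so it never fires on synthetic cohorts unless short letters are
planted deliberately. Analysis B removes its test letters from the
training pool — whether the original design did so is not stated, and the
leakage-safe reading is the only defensible one for a reimplementation.

## Synthetic cohort: what it emulates, and what it does not

Letters are bags of vocabulary *items* (words or short phrases) drawn
i.i.d. from a class-conditional categorical distribution, dressed with
light sentence scaffolding (capitalization, periods). Calibrated marginals:
site mix 1250:311; final-diagnosis mix 32.9/61.4/5.7; initially-unclear
marginal 25.6% (derived conditional probability 0.211 given a definitive
final diagnosis, since final-'unclear' letters are always initially
unclear); lengths log-normal with `mu = ln(400)`,
`sigma^2 = 2 ln(414/400)`, truncated by resampling to [63, 1070] — a
two-parameter family pinned by the two target statistics.

Effect sizes: each per-class signal item's rate is multiplied by 1.4 in
letters of its own class (uniform across the ~28-item lexicons, which
include negation and pronoun phrases so the bigram-retention machinery is
genuinely exercised). The value 1.4 was fixed by a generative calculation
before any end-to-end run: with ~60 signal items at baseline rate ~0.7
occurrences per 400-word letter, it yields a Bayes-optimal accuracy near
0.85 — a diagnosable-but-noisy task of roughly the difficulty clinical
narratives present, rather than a trivially separable one. Initially
unclear letters have effect sizes shrunk (`multiplier^0.6`): ambiguous
cases read more ambiguously, which is what makes Analysis B harder by
construction. Final-'unclear' letters draw their content class 50/50; only
their bulk statistics matter since they never enter the binary task.
Stopword items are 8x as frequent as background words, giving realistic
function-word density. A per-site background-skew knob exists but defaults
to off; nothing is known about inter-site language differences.

The generator records every letter's realized item counts, so the exact
item-level likelihood under either class is computable.
`oracle_bayes_accuracy` classifies fresh Monte-Carlo letters by the true
generative posterior log-odds and reports the fraction correct with its
binomial SE — the ceiling for any classifier trained on these corpora.

*Not emulated:* real clinical prose, Dutch morphology and grammar,
negation scope, word-order signal, longitudinal structure, inter-site
style. Consequently, passing tests show that the pipeline recovers the
statistical structure it assumes (keyword-level class signal under
realistic length/class/site marginals) — they do not show that the same
accuracy would be reached on real letters, where the embedding arm in
particular behaves very differently.

## Statistical tolerances in the tests

Bayes-consistency is asserted as: held-out accuracy within
`3 sqrt(SE_mc^2 + SE_test^2)` of the Monte-Carlo Bayes bound, on both
sides. The band combines the two sampling errors because both the bound
(Monte-Carlo, n=2000) and the accuracy (binomial, n≈293) are estimates; a
band built from the Monte-Carlo error alone would shrink to zero as the
oracle sample grows while the test-set error stays fixed, which no finite
classifier could satisfy. Marginal-calibration checks use 3 binomial SEs
at n = 10000; the planted-signal recovery check requires ≥ 90% of 40
planted features (rate multiplier 3) inside the selected 300 at n = 1200.
Fixed seeds make every stochastic test reproducible; problem sizes
(n = 1561 cohort, n_mc = 2000 oracle draws, reduced-scale determinism
re-runs) are chosen to exercise cohort-scale behavior while keeping the
full suite around a minute.

## Known limitations

* The i.i.d. item model produces a combinatorial cloud of rare background
  bigrams with no Zipfian collocation structure; feature selection on real
  text faces a different (easier) noise profile.
* The mock embedding cannot detect word-order effects, so comparisons
  between the two arms on synthetic data say nothing about the value of
  word order in real narratives.
* Published sensitivity/specificity/PPV/NPV rows are not all consistent
  with their printed confusion counts; only the count-consistent
  accuracies are reproduced.
* `exp(feature_loglik)` normalization is exact to 1e-9 per class;
  posteriors from all-zero evidence rows equal the priors exactly by
  construction.
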