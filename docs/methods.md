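# Methods

## Problem setting

Story recall is a demanding episodic-memory task: a participant hears a
short narrative and retells it immediately and again after a delay. The
pipeline treats each retelling as a text to be compared against the story
source, classifies participants from those comparisons, and quantifies what
such a classifier would buy in two screening settings — primary-care MCI
case finding and pre-screening before amyloid PET.

Four binary contrasts are evaluated: amyloid positivity in the full sample,
MCI/mild AD versus cognitively unimpaired (CU) in the full sample, and
amyloid positivity within the MCI/mild-AD and CU subsamples.

## Synthetic cohort generator

The generator emulates a 2×2 amyloid × diagnosis case–control design with
group sizes 46 (Aβ+ MCI/mild AD), 54 (Aβ− MCI/mild AD), 47 (Aβ+ CU) and
46 (Aβ− CU). Per-group age, education, MMSE and CDR-G distributions follow
the corresponding observed group summaries (e.g. Aβ+ MCI age 72.72 ± 5.95
years); normality is assumed since only means and SDs are available, ages
are truncated to the eligibility window [50, 85] and MMSE to 23–30 for
MCI/mild AD, 26–30 for CU. About 12 % of impaired participants are assigned
a mild-AD rather than MCI diagnosis. Education is missing completely at
random at rate 0.015 and PACC5 subtests at participant rate 0.115 (one to
four of the five subtests dropped), mirroring the observed missingness
levels. Missing education is imputed with the sample median (even counts:
mean of the two central values); the PACC5 composite is the mean of
available subtest z-scores and is missing (never zero) only when all five
are.

### Recall degradation model

Synthetic recalls are produced token-by-token from the normalized source
story: each token is omitted with probability `omission_rate`, otherwise
replaced by a random story-vocabulary word with probability
`substitution_rate`; after each emitted token a filled pause is inserted
with probability `filler_insertion_rate`. Delayed recall adds
`delayed_extra_omission_rate` to the omission probability.

The default ("strong") regime encodes two **separate factorial main
effects**: clinical status drives omission (0.35 impaired vs 0.10 CU) and
filler insertion (0.15 vs 0.05), while amyloid status drives substitution
(0.20 Aβ+ vs 0.04 Aβ−) and the extra delayed-recall omission (0.15 vs
0.04). Placing the two effects on distinct token operations keeps all four
contrasts linearly identifiable; when both effects load on the same
operation the full-sample amyloid contrast degenerates to an interleaved
mixture whose best attainable AUC is ≈ 0.75 regardless of sample size. A
"moderate" regime with halved contrasts is available for power and recovery
experiments.

What the generator does **not** emulate: semantic paraphrase (substitutions
are random vocabulary words, not meaning-preserving rewordings), syntactic
restructuring, discourse-level ordering errors, ASR transcription noise
beyond fillers, and any correlation between demographics and recall
quality. Passing tests therefore demonstrate that the estimation machinery
recovers structure the generator put in — not that real speech carries that
structure or that real-data accuracy would match.

## Text-pair features

Transcripts are lowercased, punctuation-stripped and whitespace-tokenized;
em/en-dashes and internal hyphens act as separators, a trailing ASCII
hyphen marks a partial word, and a configurable filler lexicon (um, uh,
er, …) is either removed or retained with a per-token flag. WER between two
token sequences is edit-distance errors per reference word, with corpus-level
and mean-over-recordings variants (the latter is the default summary).

The shipped encoder is a deterministic 16-feature surrogate for a learned
text-pair edit encoder (which would require GPU-scale pre-training and is
deliberately out of scope behind the `PairEncoder` interface): clipped
unigram/bigram precision and recall, longest-common-subsequence ratio,
length ratio (min/max), content-word precision/recall against a small
stopword list, first-occurrence ordering concordance of shared tokens,
unigram/bigram Jaccard, per-side filler and repetition rates, and
normalized edit similarity. All features lie in [0, 1]. Each story yields
six directed pair vectors — source→immediate, immediate→source,
source→delayed, delayed→source, immediate→delayed, delayed→immediate —
whose arithmetic mean is the story vector. Length ratio is defined
symmetrically (min/max, so identical texts score 1); direction sensitivity
comes from the precision/recall and per-side features. The pipeline default
keeps fillers during featurization so disfluency rates remain informative;
WER follows the filler-removal convention.

## Tournament leave-pair-out cross-validation

The hold-out unit is the participant: for every pair of participants, all
stories of the remaining participants form the training set, each story
vector labelled with its participant's label. The fold model is logistic
regression — features standardized by training-fold mean/SD, L2 penalty
with unit inverse strength `C = 1`, lbfgs with tolerance 1e-8 — an entirely
fixed configuration, so results are deterministic and order-independent.
Held-out participants are scored by simple averaging of their per-story
probabilities.

In `all_pairs` mode (default) every unordered pair is a fold; pairwise
outcomes are aggregated by win count, ties broken by mean cross-validated
score and then by participant id, and the AUC is the fraction of
opposite-label pairs the ranking orders correctly (ties ½). Win-count
aggregation was chosen over staged-knockout alternatives as the simplest
deterministic tournament rule; the ranking function is an explicit,
replaceable component. Pairs whose removal would leave a single-class
training fold (possible only with exactly two participants in a class) are
skipped rather than scored.

In `cross_label_pairs` mode only opposite-label pairs are held out and the
AUC is the classical leave-pair-out estimate — the fraction of held-out
pairs each fold orders correctly. Win-count ranking is *not* used for the
estimate there: when the two classes only ever play each other, win counts
compare within-class ranks rather than scores and inflate the AUC
(simulation: single feature with true AUC 0.76 ranked to 0.875).

Two symmetry facts worth noting: with the tournament ranking held fixed,
flipping the labels in the aggregation complements the AUC; but retraining
on flipped labels mirrors every fold's probabilities (s → 1 − s), reverses
the ranking, and returns the *same* AUC — cross-validated discriminability
is symmetric in the class labels.

Comparison models run through the identical TLPO loop: a demographic model
(age, sex as a binary indicator, years of education, one row per
participant) and a PACC5 model using the composite score directly.

## ROC inference

The AUC is the Mann–Whitney estimator via midranks. DeLong's
structural-component decomposition gives the variance (which coincides
exactly with the grouped leave-one-out jackknife, the oracle used in
tests), Wald confidence intervals, a two-sided z-test against 0.5, and the
paired test for two correlated AUCs on the same subjects. Degenerate
zero-variance cases (e.g. perfect separation) collapse the CI to a point
and return z = 0, p = 1 by documented convention rather than raising.

The Youden operating point maximizes J = Sn + Sp − 1 over midpoints between
adjacent distinct scores ("positive" means score > τ); ties in J resolve to
the higher-specificity threshold, the conservative choice for population
screening where false positives dominate the cost. Cohen's κ is computed
from the expected 2×2 table at that threshold, on pooled cross-validated
participant scores.

Power for detecting an AUC above chance uses the two-sided
normal-approximation with Hanley–McNeil exponential-model variances under
the null (0.5) and the alternative; at AUC 0.75 with 50 subjects per group
and α = 0.05 the power is 99.7 %. The binormal variance could be swapped in
but is not the default.

## Screening simulations

All screening outputs are expectations: in a population of n with
prevalence p screened by a test with sensitivity Sn and specificity Sp,
TP = npSn, FP = n(1−p)(1−Sp), PPV = TP/(TP+FP), NPV = TN/(TN+FN). An
age-stratified population is a weighted set of strata (weights summing
to 1); with operating characteristics constant across strata the pooled
result equals the single-stratum result at the pooled prevalence. A seeded
binomial-draw mode exists for uncertainty bands.

Test comparison uses **relative** changes — detection Sn_A/Sn_B − 1,
false positives (1−Sp_A)/(1−Sp_B) − 1 — because only the relative reading
of the reported +8.5 %/−59.1 % deltas reproduces the accompanying NPV of
93.6 % from the MMSE operating point (Sn 62.7 %, Sp 63.3 %) at 15.4 %
prevalence; the implied comparator is Sn 68.0 %, Sp 85.0 %.

PET pre-screening enrichment, for a target of N confirmed Aβ+ participants:
without pre-screening N/p scans; with pre-screening N/(Sn·p) recruits and
N/PPV scans, so scan reduction = 1 − p/PPV and recruitment increase =
1/Sn − 1 (a function of sensitivity alone). Prevalence presets: MCI 15.4 %
in the 65+ aggregate, Aβ+ 55.9 % within MCI and 24.9 % within CU (ages
65–85). Age-stratified prevalence tables are config slots for the user;
note that an anti-informative pre-screen (Sn + Sp < 1) can *increase* the
scan count without bound, so the "reduction ≥ −1" bound holds only for
informative tests.

## Problem sizes and numerical choices

Default analyses run at 15 participants per group (60 total, 1 770 TLPO
folds for a full-sample task), where a complete four-task experiment takes
under a minute on one CPU; the full design (193 participants, ≈ 18 500
folds per task) is supported and simply scales linearly. Estimator
validation uses 1 000-replicate coverage simulations for the DeLong CI and
a 200-participant single-feature recovery run against the closed form
AUC = Φ(δ/√2). Standardization guards zero-variance features by
substituting unit SD; Youden threshold comparisons use a 1e-12 tie
tolerance; seeds propagate through `numpy.random.default_rng` so every
output is reproducible byte-for-byte from (config, seed).

## Known limitations

The surrogate encoder measures lexical overlap only; semantic equivalence
("sofa" for "couch") is scored as an error. The degradation model's
independence assumptions (per-token, per-participant) understate the
burstiness of real disfluency and recall failure. Screening arithmetic
assumes operating characteristics transport unchanged from the evaluation
sample to the screening population. TLPO all-pairs mode is O(n²) refits;
at very large n the cross-label mode or a subsampled tournament is the
practical choice.
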