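# Methods

This note documents the measures, models and design choices behind
`veracue`, and what the synthetic-data experiments do and do not show.

## Input model

Statements are consumed as CoNLL-U dependency parses (1-based token
indices, head 0 = root), a manifest CSV carrying the design metadata
(subject, topic, veracity ∈ {truth, lie}, modality ∈ {written,
transcribed}), raw text files, and two-column TSV lexicons. The package
runs no tagger or parser itself: any conformant parser's output works,
which keeps the measurable core free of heavyweight NLP runtime
dependencies. Multiword-token ranges and empty nodes are skipped
everywhere — they have no single surface position, so they cannot enter
distance computations or token counts consistently. Every sentence is
validated as a single-rooted acyclic tree with contiguous indices before
any feature is computed.

## Complexity measures

**MDD** is the mean of |index(dependent) − index(head)| over the n−1
dependency pairs of a sentence; **MHD** is the mean number of edges on
each non-root token's path to the root. Both are undefined for
single-token sentences and are ≥ 1 otherwise. Statement-level MDD/MHD is
the unweighted mean of per-sentence values over sentences with ≥ 2
tokens: sentences are treated as exchangeable units of production. An
edge-pooled aggregation (all edges of the statement pooled before
averaging) is available via `aggregate="edge_pooled"` for users who
prefer length-weighted sentences. Punctuation tokens are kept in MDD/MHD
if the parser attached them (parsers differ in whether they do);
`exclude_punct_edges=True` removes them.

**FOG** is 0.4·(words/sentences + 100·complex/words) over the whole
statement, with words = non-PUNCT tokens and complex = words with ≥ 3
syllables. The index's classic framing assumes a ≥ 100-word passage; the
pipeline still scores shorter statements (they are legitimate analysis
units here) and logs a warning below a configurable minimum
(`fog_min_words`, default 100). The syllable counter is pluggable; the
default counts maximal vowel-letter runs with the Polish vowel set
a, e, i, o, u, y, ó, ą, ę, which merges glide sequences ("ia", "ie")
into a single nucleus and returns 0 for vowel-less strings. This is a
heuristic: real Polish hyphenation has exceptions the counter ignores,
which is acceptable because only the ≥ 3-syllable threshold enters FOG.

## Lexicon features

LCM verb classes (DAV/IAV/SV) are matched by lower-cased lemma against
the lexicon; no sense disambiguation is attempted (the dictionaries are
built to reflect each word's most frequent sense). The ADJ class counts
only adjectives modifying subject nouns, operationalized as: deprel in
the adjectival-modifier set (default {amod}) and the head token's deprel
in the subject set (default {nsubj}; scheme variants like `nsubj:pass`
can be added in `FeatureConfig`). By default an adjective must also be
listed in the lexicon's ADJ category (`adj_requires_lexicon=True`),
keeping all four classes lexicon-driven; setting it to False counts any
syntactically qualifying adjective. The general abstraction score is
DAV + 2·IAV + 3·SV + 4·ADJ.

Sentiment, negation and over-generalization features are per-statement
token counts of lemma matches. Detailed POS features count tokens by the
first ':'-segment of their XPOS tag; the default battery tracks 28
NKJP/Morfeusz tag classes. The full default battery is 43 variables:
3 length + 3 complexity + 5 LCM + 2 sentiment + 1 negation + 1
over-generalization + 28 POS. The exact membership is a configuration
artifact (`FeatureConfig.pos_tags`), not a hard-coded contract; a
`ne_count` column is appended automatically when MISC carries NE
annotations. All counts are stored unnormalized; normalization is the
statistics/classification stages' responsibility, so the feature table
remains a faithful record of raw counts.

## Statistical stage

Each dependent variable is transformed log(x+1). Count families
(LCM, sentiment, negation, over-generalization, POS, NE) are first
divided by the statement's token count, i.e. y = log(rate + 1); length
and complexity variables are transformed directly. Dividing *before*
adding 1 keeps zeros at zero and the argument positive; the alternative
order (log(count+1) then divide) would conflate statement length with
the transform and is not offered.

The model per variable is a Gaussian random-intercept regression
y = Xβ + u_subject + ε with X = (1, v, m, v·m), sum contrasts
v ∈ {−0.5, +0.5} (truth/lie) and m ∈ {−0.5, +0.5}
(written/transcribed). Fitting is REML with β and σ² profiled out
analytically (per-subject block structure makes V⁻¹ and log|V| closed
form), leaving a bounded deterministic 1-D minimization over
λ = σ_u²/σ² on [0, 10⁴] with tolerance 10⁻⁸; the λ = 0 boundary (pure
OLS) is checked explicitly. A response that OLS already fits exactly
(e.g. a constant) short-circuits to the degenerate fit with both
variances zero. The implementation reproduces an independent REML
implementation (statsmodels MixedLM) to ~10⁻⁶ on simulated data, and
collapses to OLS exactly when the subject variance is zero.

P-values are Wald normal approximations 2·Φ(−|b/se|). No
degrees-of-freedom correction is applied: with hundreds of subjects the
normal approximation is accurate, and it keeps the procedure
deterministic and assumption-light (a Satterthwaite correction would be
the natural extension for small samples). Holm's step-down correction is
applied per effect family — the set of analyzed variables within the
veracity, modality, and interaction effects separately — because each
effect answers a distinct scientific question; a pooled mode is
available. Zero standard errors (degenerate fits) yield flagged NaN
p-values rather than silent zeros.

## Classification

Count features are converted to per-token rates; each cross-validation
fold standardizes columns using training-fold statistics only, so test
rows never leak into preprocessing. Folds are grouped by subject by
default: with four statements per subject, ungrouped folding lets a
model recognize personal style rather than deception cues, inflating
accuracy; a non-grouped mode exists for comparison with protocols that
did not group. Fold assignment deals shuffled subjects round-robin into
k folds, deterministically per seed. Reported numbers are the mean fold
accuracy and its standard error sd(folds)/√k.

The built-in learner is an L2-regularized logistic regression fitted by
full-batch gradient descent with a Lipschitz step size (deterministic,
zero-initialized, intercept unpenalized); it matches scikit-learn's
penalized logistic fit on the same objective to ~10⁻³. SVM-RBF
(scikit-learn `SVC`) and gradient boosting (XGBoost, falling back to
scikit-learn's implementation) sit behind the same interface with
library-default hyperparameters; no tuning is performed anywhere.

## Synthetic corpora

The generator emulates the target study design: n subjects × 4
statements (2×2 truth/lie × written/transcribed within subject, the
spoken pair on one topic, the written pair on another; topics are
metadata labels only). Defaults were chosen once as a realistic opinion
statement profile: ~7 sentences of ~12 tokens per statement, tree-shape
0.5 (between star and chain), 25% complex filler words, and per-token
emission probabilities of 1–4% for each lexicon family. Condition
effects and per-subject intercepts (sd 0.3) act on the latent scale —
logit for probabilities, log for lengths — before the inverse link, so
the estimand of the random-intercept analysis model is known by
construction. Presets: `null` (all shifts zero), `paper_like` (moderate
shifts in the directions deception research reports: lies shorter,
simpler, more positive/less negative, more infinitives; speech longer
and deeper than writing), `strong` (large veracity shifts for
classifier stress tests).

Dependency trees interpolate star (shape 0, MHD = 1) and chain (shape
1, MDD = 1, MHD = n/2) by attaching each token to its predecessor with
probability `shape`, else to the root; heads always precede dependents,
so validity is structural. Token 1 of each sentence is a verb root and
token 2 a subject noun; LCM-adjective tokens attach amod to the subject
noun so they pass the subject-modifier filter exactly. Lemmas are
synthetic consonant-vowel strings with exact syllable counts, and all
inventories (lexicon categories, simple fillers, complex fillers) are
mutually disjoint, so every planted count is recoverable without
ambiguity. Emission families therefore apply to tokens 3..n of each
sentence; expected rates in `GroundTruth.expected_value` are per
sampled token.

What the generator does *not* emulate: real Polish morphology and word
order, topic-dependent content, discourse structure, parser and
transcription errors, and correlations between cue families beyond
those induced by shared statement length. Passing tests on synthetic
corpora therefore demonstrate that the pipeline measures what it claims
and that the statistics are calibrated under the assumed generating
process — not that any particular cue separates truth from lies in real
speech.

## Numerical and reproducibility choices

All randomness flows through `numpy.random.default_rng` seeded
explicitly; corpus generation, fold assignment, model fitting and the
CLI are deterministic given their seeds (corpora are byte-identical
across runs). The REML optimizer certificate (objective at the returned
λ beats a 50-point grid), oracle equivalences for MDD/MHD and Holm, OLS
degeneracy, seeded parameter recovery (mean β̂ within ±0.05 of a planted
0.3; ~95% Wald coverage), type-I calibration on a 400-subject null
corpus, and classifier chance-level/separability checks all run in the
test suite at the sample sizes stated there.

## Known limitations

- The Wald/normal p-values are slightly anti-conservative for very few
  subjects; the intended regime is hundreds of subjects.
- The syllable heuristic and the 28-tag battery are Polish-oriented
  defaults; other languages need a different vowel set and tag list.
- Named-entity features are a bare token count of NE-annotated tokens;
  per-type counts would need richer MISC annotations.
- LCM adjective filtering depends on the parser's subject-relation
  labels; scheme variants must be configured explicitly.
- The baseline classifier is linear; the SVM/boosting adapters exist
  precisely because stylometric signals need not be linearly separable.
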