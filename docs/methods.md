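# Methods

This note records the models implemented in `clinsbd`, the parameters that
matter, the design choices made where the design was genuinely open, and
what the synthetic corpora do and do not demonstrate.

## Classification unit and text model

The classification unit is the *period site* `L• R`: a whitespace-delimited
token `L•` whose surface ends in a period, followed by a delimiter
(whitespace, possibly containing newlines) and the next token `R`.  Periods
enclosed between two alphanumeric characters are token-internal and create
no site; the rare case of a missing space after a period is treated as out
of scope and therefore also creates no site.

Tokenization is plain whitespace splitting with two additions: newline runs
are recorded on the following token (`0`, `1`, `≥2` are the distinctions
the formatting features use), and a token containing no alphanumeric
character at all is merged into its predecessor with a single joining
space, in one left-to-right pass (so several consecutive punctuation-only
tokens fold into the same head; a punctuation-only first token stays
standalone).  A consequence of the merge is that a newline immediately
before a merged punctuation token is collapsed into the joining space; the
generator never produces such tokens, and the round-trip property is
asserted for texts without them.

Two normalizations are used throughout.  `norm(L•) = L_norm•` removes every
character that is not a Unicode letter, digit or period and collapses
adjacent periods ("(C43.5)" → "C43.5"); umlauts and ß are letters because
the target language is German.  `norm(R) = R_norm` keeps letters and digits
only ("majus." → "majus").  Both maps are idempotent.

Context strings attached to a site are raw 60-character slices of the
original text on each side of the period, truncated at text boundaries.
Snippets are interchanged as UTF-8 TSV with literal newlines and tabs
escaped.

## Corpus statistics

For every word type (the normalized left token with its terminal period
stripped) the corpus yields the counts `C(L,•)` and `C(L,¬•)`; with the
corpus totals these complete the 2×2 contingency table against `C(¬L,•)`
and `C(¬L,¬•)`.

The association between a type and a following period is measured by
Dunning's log-likelihood ratio, computed in the entropy form of the G
statistic `2 Σ O_ij ln(O_ij/E_ij)` with expected counts from the table
margins and the `0·log 0 = 0` convention.  This is algebraically the
binomial likelihood-ratio statistic `−2 log(L(H₀)/L(H_A))`; the test suite
verifies agreement with a direct evaluation of the two binomial
log-likelihoods to 1e-9 relative tolerance.  Tiny negative round-off is
clipped to 0; an all-zero table is an error.

Six scaling functions sharpen the raw statistic (`wordLength` counts
non-period characters, so internal periods never punish):

| id | form | intent |
|----|------|--------|
| S1 | `logλ · e^{C(L,•)/C(L,¬•)}` | boost period-dominant types |
| S2 | `logλ · (C(L,•)−C(L,¬•))/(C(L,•)+C(L,¬•))` | signed collocation ratio in [−1, 1] |
| S3 | `logλ · e^{−wordLength(L_norm)}` | punish long words |
| S4 | `logλ · (#internal periods + 1)` | reward internal periods |
| S5 | `logλ · wordLength(L_norm)^{−C(L,¬•)}` | punish period-free occurrences exponentially |
| S6 | `logλ + N(L_norm•)` | add dictionary prefix-match counts |

All 63 non-empty subsets of `{S1..S6}` are applied by sequential
composition in ascending index order (the order matters only because S6 is
additive) and each composition is one feature, so that feature-relevance
ranking, rather than a hand-set threshold, decides which scalings matter.

Numerical guards, none of which are dictated by the formulas themselves:
S1's denominator is floored at 1 when `C(L,¬•) = 0`, and its exponent is
clamped at 700 (just under the float64 overflow point of `exp`) so the
feature stays finite for heavily period-collocated types; S2 is defined as
0 when both counts are 0; S5 floors `wordLength` at 1 for a degenerate
empty `L_norm`.  After range scaling, an extreme S1 value simply saturates
its feature; it cannot poison the others.

The abbreviation length statistic (`µ`, `σ`, borders
`b₁ = µ+1.645σ`, `b₂ = µ+1.960σ`, `b₃ = µ+2.576σ`) is built from the types
whose period collocation is significant — `logλ` above the χ²(1 df)
critical value at `α = 0.01`, i.e. 6.635 — and period-dominant
(`C(L,•) > C(L,¬•)`).  σ is the population (divide-by-n) standard
deviation.  If no type qualifies the statistic is refused with an error
suggesting a larger corpus; a model on a tiny corpus should fail loudly
rather than carry fabricated borders.

## Lexicons

MDDict is an abbreviation-free medical dictionary: word sources are
unioned, entries ending in a period are discarded, and every known
abbreviation — terminal periods stripped — is removed.  CCDict is a
closed-class list (determiners, prepositions, conjunctions, pronouns,
auxiliaries): in German only these words are reliably lowercase, so their
capitalization marks a sentence start.

"Substring match" for S6 is implemented as a *prefix* count: ad-hoc
abbreviations are truncations, hence prefixes of their source words.  The
query `N(L_norm•)` splits `L_norm•` at periods and sums, over the
subwords, the number of lexicon entries having the subword as a prefix
(exact matches included).  Prefix matching is case-sensitive on the first
character only (truncations preserve the initial capital; German nouns are
capitalized) and case-insensitive afterwards.  Infix matching would also be
defensible; prefix semantics is the package's choice and is what the
synthetic morphology is built to exercise.

## Feature spaces

Abbreviation task, on `L_norm` (83 features plus one column per word
type): rules (internal period; contains digit; all-upper, meaning every
character is an uppercase letter, so "C43.5" and "435" do not qualify);
the four contingency counts and `logλ`; the 63 scaling compositions; the
MDDict lookup of the period-free `L_norm` (case-insensitive); the length
block (length, the three borders as per-model constants, three
above-border flags, `µ −` length); and one-hot word types with maximal
digit runs masked to `d` ("C43.5." → "Cd.d.").

Sentence task, on `R`/`R_norm`, mirroring the length and word-type blocks:
the language block (capitalized `R_norm` whose lowercase form is in CCDict
— a plain-membership variant is available behind
`ccdict_plain_membership`, the capitalization-conditioned form is the
default because only the capitalized occurrence of a function word signals
a sentence start; and `R_norm ∈ MDDict`); four rules (period in the verbatim
`R`, digit and all-upper on `R_norm`, capitalization of `R_norm`); the
newline one-hot (none/single/double, from the delimiter's newline count,
with runs ≥ 2 counted as double); the length block on `R_norm` against the
*abbreviation* length distribution; right-context and left word types; and
the abbreviation feature — the prediction of a previously trained
abbreviation model on the identical site.

Word-type vocabularies are frozen on the training sites; unseen types at
prediction time produce an all-zero block rather than an error, so no test
information leaks into the vocabulary.

## Training protocol

Features are scaled per column to `[-1, 1]` with training-set minima and
maxima (constant columns map to 0); test data is mapped with the training
parameters and may leave the range.  Each instance vector is then
normalized to unit Euclidean length (zero vectors stay zero).  The SVM is
LIBLINEAR's linear-kernel solver (scikit-learn's `LinearSVC`); the package
owns the preprocessing, protocol and ranking, not the dual optimization.

`C` is selected from the log-spaced grid
`{0.001, 0.01, 0.1, 1, 10, 100, 1000}` by stratified k-fold
cross-validation (default 3 folds inside the estimator) of the
micro-averaged F1, ties resolved toward the smallest, most regularized
value.  Selection happens on the training matrix scaled once with the
full-training parameters; re-deriving scaling per selection fold would be
marginally cleaner but changes nothing at these dimensionalities, and the
one-scaler variant matches the scale-then-search protocol the estimators
document.  Feature relevance is the squared weight `w²` of the fitted
hyperplane, sorted descending with lexicographic tie-breaks for
determinism.

Evaluation pools true/false positives/negatives over both classes into an
unweighted micro-averaged F1 — which, for a single-label binary task,
equals plain accuracy (property-tested).  Stratified 10-fold
cross-validation with a fixed seed, Cohen's κ for inter-rater agreement
(with κ ≡ 1 when both raters agree perfectly on a single label), and a
χ² comparison of two classifiers are provided.  The χ² comparison uses the
2×2 table *classifier × correct/incorrect* without continuity correction,
i.e. it compares accuracies and yields p = 1 for identical predictions; a
paired McNemar variant on the discordant counts is available via
`method="mcnemar"`.  Degenerate tables are reported as "not significant"
and flagged rather than raising.

Two rule baselines anchor the comparisons: abbreviation iff the following
character is lowercase; sentence boundary iff `R_norm` is capitalized.

The Chernoff-bound sample size `n ≥ (2+ε)/ε² · ln(2/δ)` is truncated to an
integer — the bound's conventional printed value at ε = δ = 0.05 is 3024,
which truncation reproduces (the exact bound is 3024.88).

## Synthetic corpora

The generator emulates the phenomenology of German clinical discharge
summaries: telegram-style sentences over a synthetic medical vocabulary
(noun compounds formed by stem+suffix concatenation, inflected adjectives,
a fixed closed-class list), a Zipf-weighted inventory of lexicalized
abbreviations, ad-hoc truncations of long dictionary words (guaranteed
proper prefixes of MDDict entries, which is what S6 assumes), ordinals and
dates, acronyms, ICD-like codes, decimal numbers, capitalized sentence
starts, double-newline paragraph breaks, single-newline contamination
inside sentences, and double-role periods (a sentence-final abbreviation).
Gold labels are emitted while the text is assembled and never re-derived
from the finished string, so the generator cannot share a bug with the
site extractor.

Default study conditions, fixed once: 1,500 sentences (≈3,000 sites,
matching the gold-standard scale of 3,024 snippets); per-slot rates 0.10
lexicalized abbreviation, 0.05 ad-hoc truncation, 0.04 ordinal/date, 0.04
acronym-like; paragraph rate 0.30; mid-sentence newline rate 0.15;
double-role rate 0.10.  These give roughly balanced classes (≈55%
abbreviation sites; one sentence end per sentence) and a corpus in which
the rule baselines sit far below ceiling (≈0.70 abbreviation, ≈0.77
sentence accuracy) while the statistical structure the features assume is
present.  All randomness flows from a single integer seed;
identical configs generate bit-identical corpora.

What passing on synthetic data shows — and what it does not: the synthetic
task is *easier* than real clinical text (no misspellings, no true
out-of-inventory lexicalized abbreviations, a clean vocabulary, exact
label-generating process).  High synthetic F1 therefore bounds
implementation bugs — the features compute what they claim, training
recovers the planted structure, the abbreviation feature dominates the
sentence model as expected — but it is *not* a claim about performance on
real narratives.

## Problem sizes used in the automated checks

The test suite trains on ≈3,000-site corpora with grid-selected `C` for
the parameter-recovery and stepwise checks, and uses a 120-sentence corpus
for unit-level fixtures; these sizes are the package's chosen study
conditions, at which every fit completes in seconds.

## Known limitations

* No handling of missing spaces after periods (out of scope by design);
  such periods are token-internal and invisible to the classifiers.
* The merge rule discards newline information directly preceding a
  punctuation-only token (see above).
* MDDict lookup and CCDict capitalization features assume German
  orthography (capitalized nouns, lowercase function words).
* The synthetic generator does not model misspellings, spacing errors or
  genuine lexical ambiguity of `R`; no claim of realism beyond the listed
  phenomena.
* Model persistence stores lexicons and count tables inline; for very
  large real dictionaries a file-reference scheme would be preferable.
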