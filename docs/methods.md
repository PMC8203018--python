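# Methods

`fsnlp` implements a lexicon-anchored phenotyping pipeline for one trait:
whether a clinical note documents a patient's access to firearms. This note
describes the model, the choices that were genuinely open, and what the
synthetic data can and cannot establish.

## The phenotyping model

The pipeline has five stages.

1. **Taxonomy matching.** A fixed lexicon of 27 firearm phrases (from
   single words like *rifle* to multi-word phrases like *smith and wesson*)
   is matched case-insensitively against the note's token stream. Tokens
   are maximal runs of `[a-z0-9]` after lowercasing; everything else
   separates tokens, so hyphens and slashes split ("9-mm" → `9`, `mm`).
   One normalization is applied: digit+unit fusions (`9mm`, `12gauge`,
   `45caliber`, `357magnum`) are split into two tokens, because the
   taxonomy lists spaced forms and clinical text fuses them freely. Generic
   digit/letter mixes (`m1`) are left whole. Overlapping candidate matches
   are resolved longest-match-first, then leftmost: *sniper rifle*
   suppresses the inner *rifle*. This prevents double counting; the
   alternative (count every surface occurrence) would inflate the frequency
   table for nested phrases.

2. **Snippet extraction.** Each match anchors a snippet of up to 35 tokens
   on each side of the keyphrase, truncated at note boundaries. The
   snippet, not the note, is the classifier's unit: a 70-ish-word window is
   enough context to read intent (ownership vs denial vs history) while
   excluding unrelated parts of long notes. The keyphrase's token offset
   within the snippet is retained as a feature, since position encodes
   whether the phrase opens a templated screening line or sits mid-narrative.

3. **Featurization.** Unigram and adjacent-bigram vocabularies are counted
   over the training snippets and thresholded: unigrams must occur more
   than 34 times, bigrams more than 4. The thresholds drop rare n-grams
   that would let a 200-tree forest memorize individual snippets. Features
   are binary presence indicators (not counts) plus the keyphrase offset.
   The vocabulary is fitted on the training split only by default
   (`vocab_scope="train"`); fitting on all snippets is available but leaks
   test vocabulary into training.

4. **Classification.** A random forest with 200 trees, maximum depth 15 and
   gini splits, seeded for reproducibility. Annotation is ternary
   (positive / negative / ambiguous), and the default is to train on the
   three classes and collapse AMBIGUOUS to the negative side only at
   note-level evaluation, which preserves the annotation signal while
   evaluating the binary question that matters clinically (is access
   documented or not). A binary training mode exists as a config switch.
   The 85/15 train/test split is stratified by consensus label with sizes
   fixed at round(n·f) via largest-remainder allocation, which is why it is
   implemented directly rather than delegated to a library splitter with
   floor/ceil rounding.

5. **Note aggregation.** A note with no taxonomy match is NO_MENTION.
   Otherwise every snippet is classified and the note label is any-POSITIVE,
   else any-NEGATIVE, else AMBIGUOUS. Positive precedence errs toward
   flagging access when any part of the note documents it, the conservative
   direction for a screening application.

## Agreement and adjudication

Snippets are double-annotated; agreement stands, disagreement requires an
explicit adjudicated consensus (never a silent default). Cohen's kappa is
computed from the closed-form marginal formula, on the three-category
scheme by default with a binary collapse available. The degenerate case
where both annotators are constant and identical (chance agreement = 1) is
defined as kappa 1.0; scikit-learn's implementation, which returns NaN
there, is used as an independent cross-check everywhere else.

## Reconstructing validation metrics from rounded summaries

For a binary validation set whose class sizes are known (63 positive, 175
negative), reported sensitivity and specificity rounded to one decimal in
percent usually pin down the integer confusion matrix uniquely:
`find_confusion_matrix` enumerates all (tp, tn) pairs and keeps those that
round (half-up) to the published figures. With a unique solution, accuracy
and PPV follow exactly from the cells; the package uses this to recompute
81.9% accuracy and 69.2% PPV from 57.1%/90.9% rather than asserting them.
Half-up rounding is assumed throughout; banker's rounding would change
nothing for these particular values.

## Cohort analysis

Comorbidity flags use the standard administrative-data rule: at least one
inpatient code, or two outpatient codes on separate calendar days. The rule
is order- and duplication-invariant. Code sets are caller-supplied; the
shipped `TOY_CODE_SETS` are illustrative values for simulation and tests,
not validated clinical groupings.

Documentation status is three-level (none / documentation without access /
documentation with access). Prevalence tables report counts and
column-wise percents with a chi-squared independence test attached. Two
adjusted logistic models are fitted by maximum likelihood: any mention on
the full cohort, and access among those with a mention. Reference levels
are female, under-30, White, never-smoker; ED and mental-health visit
counts enter linearly; records with missing smoking are dropped
(complete-case) from models but kept as a row in tabulations. Odds ratios
are exponentiated coefficients with 95% Wald intervals and two-sided
p-values at α = 0.05; no multiple-testing correction is applied.
Non-convergence or quasi-separation (a Wald SE above 50 on the logit scale)
raises an error naming the covariate rather than returning a silently
unstable fit.

## What the synthetic data emulates

The note generator instantiates class-specific templates — ownership
language for positive, denial for negative, historical/elsewhere language
for ambiguous (a firearm sold last year, weapon fire during deployment),
and term-free distractors emulating exposure-history documentation — each
embedded in at least 80 neutral filler words, with the leading-filler count
varied so snippet windows are exercised both truncated and interior. Gold
labels are exact by construction. The default class mix is 25% positive,
35% negative, 15% ambiguous, 25% distractor: mention-bearing notes dominate
(the corpus stands in for notes already selected by term search) with
negatives most common, as denial-style screening language is in practice.

The cohort generator samples covariates independently from marginals that
echo a first-year veteran cohort (86.93% male; 68.23% aged 30–49; 43%
PTSD; 5% missing smoking; Poisson visit counts with means 0.32 and 3.5)
and draws mention, then access conditional on mention, from logistic models
whose default log-odds echo published adjusted ORs (male 1.45 for mention,
1.19 for access, and so on), with intercepts set so the overall mention
rate is near 10% and access-given-mention near 25%. Records with missing
smoking sit at the smoking reference level in the generating linear
predictor. Diagnosis events are emitted to reconstruct the generated flags
exactly (qualifying inpatient or two-day outpatient patterns for flagged
conditions; at most one non-qualifying outpatient code for ~10% of
unflagged patients).

What passing tests show: the plumbing is correct end to end — matching,
windowing, featurization, training, aggregation, tabulation and model
fitting are mutually consistent, deterministic under fixed seeds, and the
regression recovers known parameters. What they do not show: performance
on real clinical text. The templates are lexically separable by design, so
near-perfect held-out accuracy is a plumbing check, not a claim about the
harder distribution of real notes, where reported accuracy is in the low
80s. Covariate independence in the cohort generator likewise understates
the collinearity of real comorbidity data.

## Problem sizes and numerics

Default test-time sizes are chosen to make the statistical checks
well-powered while remaining quick on a single CPU: 2,000 notes
(≈1,500 snippets) for the pipeline properties, 50,000 patients for
parameter recovery (3-SE criterion on every generating coefficient of both
models), and 100 replicates of 20,000 patients for null CI coverage
(per-term coverage of OR = 1 must reach 90/100). Kappa's degenerate-margin
case, NaN (not 0) for undefined metric denominators, lexicographic
vocabulary ordering for stable feature indices, and seeded RNGs everywhere
are the main numerical conventions; ties in the largest-remainder split
allocation break by class name for determinism.

## Known limitations

- Negation and section structure are learned implicitly by the classifier,
  never modelled explicitly; a "denies access to firearms" inside a copied
  template will be handled only as well as the n-grams allow.
- English-only tokenization; non-ASCII casefolding subtleties are ignored.
- The taxonomy is fixed input; building or extending it from clinical
  vocabularies is out of scope.
- Model persistence is limited to in-process handles; the CLI retrains
  within a run rather than shipping a versioned binary artifact.
- Quasi-information-criterion model diagnostics are not implemented; the
  fit object's standard errors and convergence flags are the only
  diagnostics exposed.
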