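# fsnlp

Detecting documentation of firearm access in clinical notes, and analysing
who gets screened.

Routine provider screening for firearm access is a lethal-means-restriction
strategy for suicide prevention, but whether such conversations are
actually documented in the electronic health record is hard to measure:
the evidence sits in free-text notes, not coded fields. `fsnlp` is a
phenotyping pipeline for that problem, aimed at health-services and
informatics researchers. It finds occurrences of a 27-phrase firearm
taxonomy in note text, cuts a 35-word context window around each match,
classifies the window with an n-gram random forest as documenting access
(positive), documenting no access (negative) or ambiguous, aggregates to a
note-level label, and then analyses documentation prevalence across a
patient cohort with adjusted logistic models.

## Method

For a note with token sequence $t_1,\dots,t_L$ and a taxonomy match at
tokens $[s, e)$, the snippet is
$t_{\max(0,s-w)},\dots,t_{\min(L,e+w)-1}$ with $w = 35$. Snippet features
are binary indicators over a vocabulary of unigrams with corpus frequency
$> 34$ and adjacent bigrams with frequency $> 4$, plus the keyphrase's
token offset; the classifier is a seeded random forest (200 trees, depth
15, gini) trained on an 85/15 stratified split of double-annotated,
consensus-adjudicated snippets. A note is labelled by any-positive
precedence over its snippet labels (NO_MENTION if no match). Agreement is
Cohen's $\kappa = (p_o - p_e)/(1 - p_e)$. Cohort analysis flags
comorbidities by the $\ge 2$ outpatient (separate days) / $\ge 1$ inpatient
code rule and fits two logistic models — any mention, and access among
mentions — reporting $e^{\hat\beta}$ with 95% Wald intervals.

Because real clinical corpora of this kind are not public, the package
includes first-class synthetic generators: template-based notes with exact
gold labels, and a cohort whose mention/access indicators follow known
logistic models, so every stage is testable end to end.

## Worked example

```python
import fsnlp

lexicon = fsnlp.Lexicon.default()          # the 27-phrase taxonomy
note = ("Routine follow up. Veteran reports he cleaned his SNIPER RIFLE this "
        "weekend and keeps a 9mm Glock in the nightstand.")

for m in fsnlp.find_term_matches(note, lexicon, note_id="demo"):
    print(m.term_text, m.token_start)
# sniper rifle 8      <- the inner "rifle" is suppressed (longest match wins)
# 9 mm glock 15       <- "9mm" is normalized to the spaced taxonomy form
```

Training on synthetic data (see `examples/03_train_and_classify.py`):

```text
1532 labelled snippets from 2000 notes
vocabulary: 177 unigrams, 3420 bigrams
held-out snippet accuracy: 1.000
note000000: predicted=positive   gold=positive
```

Held-out accuracy near 1.0 says the plumbing is consistent — the synthetic
classes are separable by construction — not that real notes are this easy.
Cohort analysis (see `examples/04_cohort_models.py`):

```text
mention rate: 10.5%  access|mention: 25.6%
adjusted male mention OR: 1.50 (95% CI 1.36-1.66); generating OR 1.45
```

The fitted odds ratio recovers the value the generator used, which is the
package's check that the regression layer is sound.

The `examples/` directory has one short script per capability:
matching/snippets, agreement, training/classification, cohort models, and
validation-metric reconstruction. A thin CLI mirrors the stages:

```bash
fsnlp simulate notes --n 2000 --seed 11 --out corpus.jsonl --gold gold.csv
fsnlp match --notes corpus.jsonl --out matches.jsonl --counts term_counts.csv
fsnlp kappa --annotations ann.csv
fsnlp run --config run.yaml        # full pipeline with a JSON manifest
```

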