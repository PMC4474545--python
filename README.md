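# clinsbd

Period disambiguation in clinical narratives: abbreviation detection and
sentence-boundary detection with linear SVMs.

## The problem

In German clinical free text the period character is heavily overloaded.
Besides ending sentences it terminates abbreviations — which in German
*must* carry a terminal period ("St.p.", "ca.", "Pat."), including ad-hoc
truncations of long compounds ("Tumordurchm." for "Tumordurchmesser") and
ordinals ("3." = "third") — and it appears inside dates ("3.5.2014"), codes
("C43.5") and ill-formed agglutinations ("sek.knot.SSM").  Discharge
summaries are telegram-style and noisy, so naive sentence splitters break
badly, and everything downstream (section detection, information
extraction) breaks with them.

`clinsbd` frames the problem as two binary classifications over *period
sites* `L• R` — a whitespace-delimited token `L•` ending in a period,
followed by the next token `R`:

* **abbreviation detection** — is the period an abbreviation marker?
* **sentence-boundary detection** — does the period delimit a sentence?

A single period can be both at once (a "double-role" period: an
abbreviation that ends the sentence).

## The method

Both classifiers are linear-kernel SVMs, `f(x) = sgn(wᵀx + b)`, trained on
features scaled to `[-1, 1]` and instance vectors normalized to unit
length, with the cost parameter `C` selected on a logarithmic grid in
`[0.001, 1000]` by stratified cross-validation of the micro-averaged F1.
Feature relevance is ranked by squared weight `w²`.

The abbreviation feature space combines six switchable sets computed on the
normalized left token `L_norm`: rule features (internal period, digit,
all-uppercase), the corpus contingency counts `C(L_norm,•)`, `C(L_norm,¬•)`,
`C(¬L_norm,•)`, `C(¬L_norm,¬•)` together with Dunning's log-likelihood
ratio `logλ = −2 log(P(H₀)/P(H_A))` for the word–period collocation, all 63
non-empty compositions of six scaling functions `S1..S6` of `logλ`
(period-collocation ratio, word length, internal periods, dictionary prefix
matches), a lookup in an abbreviation-free medical dictionary (MDDict),
length features against the corpus abbreviation-length distribution
(borders `b₁ = µ+1.645σ`, `b₂ = µ+1.960σ`, `b₃ = µ+2.576σ`, where
`wordLength` counts non-period characters: `wordLength("St.p.") = 3`), and
one-hot word types with digit runs masked to `d`.

The sentence feature space mirrors this on the right token `R_norm`
(capitalized closed-class word, MDDict lookup, rules, single/double/no
newline before `R`, length features, left and right word types) and adds
the trained abbreviation model's prediction on the same site as a feature —
abbreviations tend to sit inside sentences, so this is the strongest single
cue.

The real corpus behind the original study (dermatology discharge
summaries) is not redistributable; `clinsbd.synth` generates seeded
synthetic corpora with the same phenomenology (lexicalized and ad-hoc
abbreviations, ordinals, dates, acronyms, ICD-like codes, newline
contamination, double-role periods) with gold labels emitted at generation
time, so the whole pipeline trains and evaluates without external data.

## Worked example

```python
import numpy as np
from clinsbd import (
    AbbreviationDetector, SentenceBoundaryDetector,
    count_collocations, generate_corpus, generate_lexicons,
    extract_period_sites, tokenize, micro_f1,
)
from clinsbd.synth import GeneratorConfig

mddict, ccdict = generate_lexicons(seed=0)
text, gold = generate_corpus(GeneratorConfig(n_sentences=1500, seed=0), mddict, ccdict)
table = count_collocations(tokenize(text))
y_abbrev = np.array([int(s.is_abbrev) for s in gold])
y_sentence = np.array([int(s.is_sentence_end) for s in gold])

abbrev = AbbreviationDetector(mddict=mddict, count_table=table).fit(gold, y_abbrev)
sentence = SentenceBoundaryDetector(
    mddict=mddict, ccdict=ccdict, count_table=table, abbrev_model=abbrev
).fit(gold, y_sentence)

print("abbrev  C =", abbrev.C_, " training micro-F1 =",
      round(micro_f1(abbrev.predict(gold), y_abbrev), 3))
print("sentence C =", sentence.C_, " training micro-F1 =",
      round(micro_f1(sentence.predict(gold), y_sentence), 3))
for i, r in enumerate(sentence.rank_features(3), 1):
    print(f"{i}  {r.name:14s} w^2 = {r.w2:8.2f}")

snippet = ("St.p. exulz. Melanom li. Kontrolle o.B.\n\n"
           "Keine Hautveränderung. Der Befund ist reizlos, "
           "Tumordurchmesser 2,42 mm")
sites = extract_period_sites(tokenize(snippet), snippet)
for s, a, e in zip(sites, abbrev.predict(sites), sentence.predict(sites)):
    print(f"{s.left_token:16s} abbrev={a} sentence_end={e}")
```

prints

```
abbrev  C = 1.0  training micro-F1 = 1.0
sentence C = 100.0  training micro-F1 = 0.986
1  Abbreviation   w^2 =  1643.12
2  in_CCDict      w^2 =   862.39
3  Double_newline w^2 =   572.10
St.p.            abbrev=1 sentence_end=0
exulz.           abbrev=1 sentence_end=0
li.              abbrev=1 sentence_end=0
o.B.             abbrev=1 sentence_end=1
Hautveränderung. abbrev=0 sentence_end=1
```

Reading the output: both models are fitted on ~3,000 synthetic period
sites; `C` is the grid-selected cost.  The sentence model's most relevant
feature by `w²` is the abbreviation model's prediction, followed by the
capitalized-closed-class-word cue and the paragraph (double newline)
marker.  On the snippet, the lexicalized ("St.p.", "li."), ad-hoc
("exulz.") abbreviations are recognized as non-boundaries; "o.B." is a
double-role period (abbreviation *and* sentence end, before a paragraph
break); "Hautveränderung." is a plain sentence delimiter; the periods in
"2,42" and inside tokens create no sites at all.

The same pipeline is available from the shell:

```bash
clinsbd generate --out-dir corpus --n-sentences 1500 --seed 0
clinsbd train --task abbrev --snippets corpus/gold.tsv --corpus corpus/corpus.txt \
              --mddict corpus/mddict.txt --out abbrev.json
clinsbd train --task sentence --snippets corpus/gold.tsv --corpus corpus/corpus.txt \
              --mddict corpus/mddict.txt --ccdict corpus/ccdict.txt \
              --abbrev-model abbrev.json --out sentence.json
clinsbd classify note.txt --abbrev-model abbrev.json --sentence-model sentence.json
clinsbd rank --model sentence.json -n 10
```

`clinsbd sample` draws annotation snippets from a raw corpus, sized by the
distribution-free Chernoff bound `n ≥ (2+ε)/ε² · ln(2/δ)` (3024 snippets at
ε = δ = 0.05) when `--n` is not given.

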