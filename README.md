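# abstractqual

Linguistic profiling and supervised topic modelling of randomized-controlled-trial
(RCT) abstracts against risk-of-bias quality labels.

The package implements a complete analysis pipeline:

1. **Corpus model** (`abstractqual.corpus`) — document/record data model,
   CSV/JSONL corpus I/O, tokenization, sentence splitting, coarse POS
   classing (pluggable backend with a frozen deterministic lexicon fallback),
   and binarization of 12-item Cochrane-style risk-of-bias scores into a
   binary quality label (high quality ⇔ ≥ 6 "yes" items; threshold
   configurable).
2. **Linguistic features** (`abstractqual.features`) — characters/word,
   words/sentence, sentences per 100 words, word count, noun/verb/conjunction
   proportions, Flesch Reading Ease, Herdan's C (LogTTR), and ranked
   unigram/bigram tables (lowercased, stop-worded, Porter-stemmed; bigrams
   stay within sentences).
3. **Group inference** (`abstractqual.group_stats`) — Welch's t test between
   quality groups and Pearson correlation of each feature with the yes-item
   count, assembled into a comparison table.
4. **Supervised topic model** (`abstractqual.slda`) — LDA with a logistic
   quality response (topics + trial covariates), fit by stochastic-EM
   collapsed Gibbs sampling (numba-accelerated, fully seeded).  Includes
   topic-number selection by stratified 10-fold CV on AUC, bidirectional AIC
   stepwise selection over covariate blocks, per-topic odds-ratio tables
   (topic 1 = reference), and top-word listings.
5. **Evaluation** (`abstractqual.evaluation`) — AUC (Mann-Whitney), Brier
   score, Hosmer-Lemeshow calibration test (10 groups), PPV/NPV with an
   explicit positive class and threshold.
6. **Synthetic corpora** (`abstractqual.synthetic`) — generator with known
   ground truth (topics, mixtures, response coefficients, covariates,
   risk-of-bias records, surface text) plus parameter-recovery diagnostics.
7. **Pipeline/CLI** (`abstractqual.pipeline`, `abstractqual.cli`) —
   end-to-end orchestration producing a deterministic report bundle.

## Tests

```bash
python -m pytest -q tests/
```

Note: one acceptance test (quality-label counts) requires the published
supplementary per-article score table, which is **not** redistributable and
is therefore not bundled; that single test fails unless you place the CSV at
`data/supplementary/pone.0173526.s002.csv`.  Everything else runs
self-contained (synthetic fixtures are generated at test time).

## CLI

```bash
# generate a synthetic corpus with known truth
abstractqual simulate --seed 1 --out-corpus corpus.jsonl --out-table corpus.csv

# individual stages
abstractqual features corpus.jsonl --out features.csv
abstractqual ngrams corpus.jsonl -n 2 --out bigrams.csv
abstractqual compare-groups corpus.jsonl --out comparison.csv
abstractqual select-k corpus.jsonl --k-grid 2,3,4,5,6 --out cv.csv
abstractqual fit corpus.jsonl -k 4 --out model.json
abstractqual stepwise corpus.jsonl model.json --out refit.json
abstractqual evaluate predictions.csv --out report.json

# everything at once
abstractqual run-all corpus.jsonl --out-dir out/
```

`run-all` writes: per-document feature CSV, group-comparison CSV,
group-level Herdan's C, ranked n-gram tables, the CV table with the chosen
topic count, the fitted model JSON, top-words and odds-ratio tables, an
evaluation report, and a manifest stamped with the config hash and seed.
Identical config + seed ⇒ byte-identical bundles.

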