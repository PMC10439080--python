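# picnorm

A pipeline for **picture-naming norming studies**: the behavioural
experiments in which participants name pictures of objects and actions,
and the resulting responses, latencies, and ratings are aggregated into
a normed stimulus database and analysed for predictors of naming speed.

`picnorm` is aimed at psycholinguists preparing such a database (or
validating analysis code for one). It implements the full chain:

1. **coding** — classify each trial as *valid*, *invalid*, or
   *no response*; unify verb responses (raw form → infinitive → merged
   aspect/reflexive variants); assign Lexical Codes 1–4 (dominant name,
   same-root variant, synonym, other) from explicit lookup tables;
2. **agreement** — per-picture name distributions with the two standard
   name-agreement indices: NA% (share of the modal name) and the
   H statistic, the Shannon entropy of the name distribution,

   H = Σᵢ pᵢ log₂(1/pᵢ),   i = 1…k distinct names,

   which is 0 for unanimous naming and log₂(k) for a uniform split;
3. **complexity** — the Complexity Index, a composite word-difficulty
   score: a doubled class-standardized phoneme-length term
   2·(length − mean)/SD plus phonology points (initial
   fricative/affricate, initial cluster, medial clusters), morphology
   points (1 per stem, derivation, prefix/suffix) and exposure points
   (availability, preschool access, loanword);
4. **norms** — rating aggregation (goodness of depiction, image
   agreement, concept familiarity, imageability, age of acquisition),
   alternative-name retention (≥5 users for nouns, ≥8 for verbs), and
   the two summary tables (dominant-only and dominant+alternatives)
   with descriptive statistics;
5. **inference** — skewness-driven transformations (−1000/RT for
   latencies, inverse/√/log for predictors), Spearman correlation
   matrices and Wilcoxon rank-sum class comparisons with Bonferroni
   control, VIF collinearity screening, and a linear mixed-effects
   model of transformed latency with crossed random intercepts for
   participants, pictures, and alternative names within pictures;
6. **simulate** — a synthetic-data generator with known ground truth
   (Dirichlet-categorical name distributions, outcome rates, a latency
   model that exactly inverts the analysis model) so every stage can be
   tested without access to restricted raw data.

## Worked example

```python
from picnorm.agreement import NameDistribution, entropy_h, percent_na, dominant_name
from picnorm.complexity import WordFeatureRecord, complexity_index

# 95 valid naming responses for one picture
dist = NameDistribution.from_counts({"samochód": 62, "auto": 28, "wóz": 5},
                                    picture_id="car")
print(percent_na(dist))    # 65.26  -> 65.26% of namers used the modal name
print(entropy_h(dist))     # 1.145  -> naming entropy in bits (0 = unanimous)
print(dominant_name(dist)) # ('samochód', False)  -> modal name, no tie

# Complexity Index of a 4-phoneme loanword noun with standardized
# length (length - class mean)/SD = -0.947
rec = WordFeatureRecord(word="auto", word_class="noun", phoneme_count=4,
                        preschool_access="very_often", is_loanword=True)
print(complexity_index(rec, length_term=-0.947).ci)  # 0.106
```

NA% is the percentage of valid responses matching the dominant name;
H weighs *how* the remaining responses spread over alternatives (here
1.145 bits, a moderately contested picture). The CI of 0.106 decomposes
as 2·(−0.947) for its short length + 1 stem point + 1 loanword point.

An end-to-end run on synthetic data (simulate → code → agreement →
complexity → norms → analyse, with a reproducibility manifest):

```bash
picnorm run --config config.yaml --seed 7 --out results/
# or in Python:
# from picnorm.pipeline import run_pipeline
# run_pipeline({"simulation": {"n_participants": 60}}, "results/", seed=7)
```

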