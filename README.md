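# polarlex

Tools for quantifying **partisan polarization in short political texts
about vaccination** — built for infodemiology and health-communication
researchers studying how legislators of different parties talked about
vaccines on social media during the COVID-19 era.

The pipeline mirrors a complete observational text-mining study:

1. **Lexicon filtering** — keep tweets matching a configurable vaccine
   lexicon (default: stem-prefix matching on `vaccin`, `vax`, `immuniz`,
   `inoculat`, …) inside a study window, and tag mentions of COVID-19
   and of non-COVID infectious diseases.
2. **Descriptive statistics** — party shares, retweet and disease-mention
   rates, and Pearson χ² tests of party × tweet characteristic.
3. **Differential term usage** — document frequency of every unigram and
   bigram used by ≥0.1% of either party's tweets, per-term χ² tests with
   a Bonferroni-corrected cutoff (*P* < .001 familywise), and the D-vs-R
   log-frequency scatter layout; repeatable within pandemic waves.
4. **Topic modeling** — latent Dirichlet allocation fitted from scratch
   by collapsed Gibbs sampling (numba-compiled, seeded, multi-restart),
   with UMass coherence for choosing the topic count and top-word /
   top-tweet review sheets.
5. **Partisan metrics** — mean topic representation by party and period
   (mean topic probability × 100%), per-topic rank tests, and the
   monthly **polarization index**

   &nbsp;&nbsp;&nbsp;&nbsp;P(m) = Σₖ | rep_D(k, m) − rep_R(k, m) | ∈ [0, 200],

   the sum over topics of the absolute difference in mean topic
   representation between the parties, plus pandemic-wave segmentation
   at the nadirs of the 7-day moving average of new cases.

Because raw legislator-tweet corpora are not redistributable, the
package ships a first-class **synthetic corpus generator** that plants
known structure — party-specific topic mixtures drifting over months,
unequal party volumes, retweet and disease-tag rates — so that every
stage can be validated against ground truth.

## Worked example

Simulate a corpus with a planted partisan gap and run the pipeline:

```bash
cat > spec.yaml <<'YAML'
n_tweets: 3000
n_topics_true: 5
vocab_size: 500
topic_word_concentration: 0.05
mixture_concentration: 0.5
doc_length_mean: 15
months: ["2020-03", "2020-06", "2020-09"]
party_topic_mixtures:
  D: [0.40, 0.25, 0.15, 0.10, 0.10]
  R: [0.10, 0.10, 0.15, 0.25, 0.40]
seed: 7
YAML
polarlex simulate --spec spec.yaml --out corpus.jsonl --truth truth.json

cat > run.yaml <<'YAML'
corpus_path: corpus.jsonl
out_dir: run
n_topics: 5
lda_alpha: 0.1
lda_iterations: 300
lda_burn_in: 150
seed: 7
YAML
polarlex run --config run.yaml
polarlex report --run-dir run
```

The run directory then contains, among other artifacts,
`polarization.csv`:

```
month,value,n_D,n_R
2020-03,87.27,584,403
2020-06,84.82,621,370
2020-09,85.89,600,394
```

The planted mixtures above imply a true polarization of
Σ|Δ| × 100 = 90 in every month; the index recomputed from the fitted
topic model lands within a few points of it.  `topic_summary.csv` shows
the fitted topics with their per-party representation:

```
topic,rep_D,rep_R,significant
0,25.17,10.95,True
1,9.86,39.33,True
2,16.07,15.01,False
3,10.62,24.07,True
4,38.28,10.64,True
```

Fitted topics are an arbitrary permutation of the planted ones: the two
strongly Democratic-leaning planted topics (40% and 25% mass) and the
two Republican-leaning ones are recovered and flagged significant, while
the symmetric 15% topic is — correctly — not.  Per-party
representations sum to 100 within rounding.

Every command is also available as a library call (`polarlex.generate_corpus`,
`polarlex.fit_lda`, `polarlex.polarization_series`, …).

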