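# Methods

## Study design being modeled

The package operationalizes a tweet-level observational design: all
tweets by state and federal legislators that match a vaccine lexicon
within a fixed study window (defaults: 2020-02-01 through 2020-12-11,
both endpoints inclusive, timestamps compared in UTC) form the analysis
corpus.  The tweet — not the legislator — is the unit of analysis
throughout; retweets are retained as ordinary records with a flag, and
tweets from independent or unknown-party authors are generated and
counted but excluded from every partisan comparison.

## Lexicon filtering

Inclusion requires at least one token matching the vaccine term set.
Two matching modes exist:

* `stem_prefix` (default) — a token matches if it begins with one of
  the stems {`vaccin`, `vax`, `immuniz`, `immunis`, `inoculat`,
  `innoculat`, `antivax`, `anti-vax`}.  This is the shipped default
  because surface-form lists demonstrably miss inflections that a study
  corpus would include ("vaccinated", "vaccines", "#VaccinesWork"
  after hashtag stripping).
* `exact_word` — token equality against the literal term list with
  parenthetical spellings expanded ("vax(x)" → vax, vaxx), retained for
  strict replication.

COVID-19 and non-COVID disease tagging use explicit word lists
(config-first, with defaults such as {covid, covid-19, coronavirus,
sars-cov-2, …} and {flu, influenza, measles, mmr, hpv, polio, smallpox,
fluseason}) matched as exact words, since prefix matching on very short
disease names ("flu") would overreach.  The three flags are independent;
a tweet can mention both disease classes.  A manual-relevance review
step is modeled as an optional exclusion-term list (default empty).

Normalization lowercases, strips URLs, @-handles, a leading "rt"
marker, and `#` characters (keeping the tag word), and splits on
punctuation.  Hyphenated compounds are indexed both whole
("anti-vaxxers") and as parts ("anti", "vaxxers").  Sentence-final
punctuation is remembered so bigrams never span sentences.

## Differential term usage

"Frequency" is document frequency: the share of a party's tweets
containing the term at least once, matching the tweet-level design; a
token-share variant is available via `count_mode="token"`.  The 0.1%
floor keeps a term if it reaches the threshold in *either* party
(`denominator="per_party"`; a pooled denominator is available).
Stopwords are kept — common words can be partisan signals — and no
stemming is applied, so inflected surface forms are tested as they
occur.  Each retained term is tested with the Pearson χ² on its
2×2 contains/not-contains × party table; the Bonferroni family is the
number of retained terms, so the per-term cutoff is α/m with α = .001.
Exactly tied proportions give a null direction.  Degenerate tables
(term in all or no tweets) receive p = 1 rather than an error so bulk
runs never abort.

## Topic model

LDA is fitted by collapsed Gibbs sampling implemented in a
numba-compiled kernel: per token, the assignment is resampled from
p(z=k) ∝ (n_kw+β)/(n_k+Vβ)·(n_dk+α) with the token excluded from all
counts.  Numerical choices:

* **Posterior summary** — φ and θ are means of thinned post-burn-in
  count snapshots (every 10 iterations by default), not a single final
  state; this is markedly more stable for short documents.
* **Restarts** — collapsed Gibbs occasionally sticks in a local mode
  where two planted topics merge and a third splits.  Stuck chains have
  clearly lower joint log-likelihood, so `fit_lda` runs `n_restarts`
  (default 3) independent chains with derived seeds and keeps the one
  with the highest mean post-burn-in log-likelihood.  The whole
  procedure is deterministic in the seed.
* **Hyperparameters** — defaults α = 50/K, β = 0.01 (common practice);
  for short documents (~15 tokens) the benchmark settings use α = 0.1,
  because 50/K pseudo-counts per topic would dominate a 15-token
  document and flatten its topic posterior.
* **Vocabulary** — a standard English stopword list is removed, then
  terms in fewer than `min_doc_freq`=2 documents or more than
  `max_doc_prop`=50% of documents are pruned; documents emptied by
  pruning are dropped with their ids logged.
* **Log-likelihood** — the trace records the collapsed joint
  log p(w, z) each iteration; its trend (mean of the last 10% vs the
  first 10%) is asserted non-decreasing in tests.

Topic-count selection fits one model per K on a grid (same seed policy),
scores each by mean per-topic UMass coherence —
Σ_{m>l} log((D(w_m,w_l)+1)/D(w_l)) over the topic's top 10 words, using
document frequencies from the fitted corpus itself — and recommends the
argmax.  Because coherence alone cannot settle interpretability, the
selector also emits a review sheet (top 10 words, top 10 tweets per
topic, plus a seeded 20-tweet random sample per topic) for human
judgment.  Downstream analyses accept an `included_topics` list so a
manually curated subset can replace the full set; the default is all
topics.

## Partisan metrics

Mean topic representation for a (party, period) stratum is the
elementwise mean of the stratum's θ rows × 100; by construction the
values sum to 100 over topics, which bounds the monthly polarization
index P(m) = Σₖ|rep_D − rep_R| at 200.  Months missing either party
yield a missing point — never a silent zero, which would fabricate
consensus.  The partial final month of the default window (Dec 1–11) is
a valid short period.

The party-difference test on topic probabilities is, by default, the
two-sample Wilcoxon rank-sum on per-tweet topic probabilities (D vs R),
Bonferroni-corrected over the included topics.  The pairing unit of a
signed-rank formulation is genuinely ambiguous for unpaired party
groups, so a paired signed-rank variant over monthly (D, R)
representation pairs is provided via `method="signed_rank_monthly"`;
neither variant is claimed to be the exact historical procedure.

Wave segmentation computes the trailing 7-day moving average of daily
new cases and places boundaries at its interior local minima (first
index of any plateau), keeping the n−1 deepest nadirs for n waves with
first-occurrence tie-breaks.  A monotone series yields a single wave
with a warning.

## Synthetic corpus generator

The generator emulates the statistical skeleton of a partisan
legislator-tweet corpus: a ~62/37/1 D/R/I party split; per-party
retweet probabilities (~0.40 D, ~0.37 R); per-party COVID (~0.53/0.58)
and non-COVID (~0.14/0.08) tag probabilities; short documents with
Poisson(15) lengths truncated at 3 tokens (3 keeps bigram extraction
nondegenerate); and per-document topic mixtures drawn
Dirichlet(c·mean) around party- and month-specific planted means, with
words drawn from Dirichlet topic-word distributions over an abstract
vocabulary.  Independents draw from the midpoint of the two party
means.  A vaccine-lexicon token is *appended* (never substituted) when
a document lacks one, so the filter contract holds without distorting
planted topic proportions; COVID/flu filler tokens are appended the
same way.  Timestamps are uniform within calendar months (UTC).
Per-month volumes are configurable and default to an even split.

What the generator does **not** emulate: English syntax, hashtag
semantics, retweet cascades, author-level clustering, or vocabulary
burstiness.  Passing recovery tests therefore shows the pipeline's
statistical machinery is correct under its own model assumptions — not
that a particular historical corpus would yield particular topics.

Two standard experiment specs are provided:

* `benchmark_spec` — K*=5 topics, V=500, 2,000 tweets, mean length 15,
  sparse topics (word concentration 0.05) and sparse mixtures
  (concentration 0.5) around fixed party means
  D=(.40,.25,.15,.10,.10), R=(.10,.10,.15,.25,.40) (planted
  polarization 90).  With 500 Gibbs iterations the Hungarian-matched
  mean cosine between fitted and planted topics is ≈0.99.
* `vshape_spec` — ten months whose planted polarization falls from 60
  to 18 over the first three months and rises to 87 thereafter.
  Trend recovery is judged qualitatively (`v_shape_recovered`): all
  down-phase first differences negative and at most one rising-phase
  difference non-positive.  The late-window planted steps (+9 points)
  sit near the Monte-Carlo noise of a 2,000-tweet month, so demanding
  every month-to-month sign would test the noise floor rather than the
  trend; the qualitative criterion matches the planted shape — an early
  decline, then a rise through most of the window.

## Problem sizes used in validation

Tests and the acceptance script scale experiments to desk size: the
2,000-document benchmark for recovery and K selection (20 replicates at
300 iterations for the selection hit rate), a 27,000-document two-month
corpus (~5,000 tweets per party per month) for planted-vs-estimated
polarization agreement, 10 replicates of the V-trend corpus, 100
replicates of the 5%-vs-1% planted-term power study, and 200 label
shuffles for the familywise-error check.

## Known limitations

* Tweet-level tests ignore repeated tweets per legislator; clustering
  by author would widen intervals.
* The polarization index ignores tone: opposing stances inside one
  topic are invisible to it, so it is a lower bound on substantive
  disagreement.
* UMass coherence is corpus-intrinsic; it ranks topic quality without
  any claim of human-judged interpretability.
* The Gibbs sampler is single-threaded; corpora far beyond ~10⁵
  documents will be slow at high K.
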