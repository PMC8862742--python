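"""Synthetic tweet corpora with known ground truth.

Emulates the statistical structure of a partisan legislator-tweet corpus:
two-party authorship with unequal volume, tweet/retweet flags, short
mixed-topic documents drawn from party-specific topic mixtures that drift
over months (planting a polarization trend), and a vaccine-lexicon term in
every document so the inclusion filter passes them.  Tokens are abstract
vocabulary items ("w0001", ...) plus lexicon terms — no attempt is made to
mimic real English.

The ground truth (per-document topic mixtures, topic-word distributions,
planted monthly polarization) is returned alongside the corpus so every
downstream stage can be tested for parameter recovery.
"""

from __future__ import annotations

import calendar
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone
from pathlib import Path

import numpy as np

from .ingest import TweetRecord, normalize

logger = logging.getLogger(__name__)

PARTY_ORDER = ("D", "R", "I")

#: Corpus-level defaults mirroring the study conditions: ~62/37/1 party
#: split; retweet shares around 40% (D) and 37% (R); COVID-term shares
#: around 53% (D) and 58% (R); non-COVID-disease shares 14% (D) / 8% (R).
DEFAULT_PARTY_SPLIT = (0.618, 0.372, 0.010)
DEFAULT_RETWEET_PROB = {"D": 0.403, "R": 0.369, "I": 0.39}
DEFAULT_COVID_PROB = {"D": 0.532, "R": 0.583, "I": 0.55}
DEFAULT_NONCOVID_PROB = {"D": 0.144, "R": 0.075, "I": 0.11}

VACCINE_FILLER = "vaccine"
COVID_FILLER = "covid"
NONCOVID_FILLER = "flu"


class ConfigurationError(ValueError):
    """A corpus spec field violates its invariants."""


@dataclass
class SyntheticCorpusSpec:
    """Configuration for one synthetic corpus.

    ``party_topic_mixtures`` maps each party to either a single length-K*
    probability vector (used for every month) or a list of one vector per
    month — the planted Dirichlet mean of each document's topic mixture.
    Document topic mixtures are Dirichlet(mixture_concentration * mean);
    topic-word distributions are Dirichlet(topic_word_concentration)
    draws over the abstract vocabulary.
    """

    n_tweets: int = 2000
    party_split: tuple[float, float, float] = DEFAULT_PARTY_SPLIT
    n_topics_true: int = 5
    vocab_size: int = 500
    topic_word_concentration: float = 0.05
    party_topic_mixtures: dict = field(default_factory=dict)
    mixture_concentration: float = 1.0
    doc_length_mean: float = 15.0
    months: list[str] = field(default_factory=lambda: ["2020-06"])
    retweet_prob: dict = field(default_factory=lambda: dict(DEFAULT_RETWEET_PROB))
    covid_tag_prob: dict = field(default_factory=lambda: dict(DEFAULT_COVID_PROB))
    noncovid_tag_prob: dict = field(default_factory=lambda: dict(DEFAULT_NONCOVID_PROB))
    tweets_per_month: list[int] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_tweets < 1:
            raise ConfigurationError("n_tweets must be positive")
        if self.n_topics_true < 2:
            raise ConfigurationError("n_topics_true must be >= 2")
        if self.vocab_size < 10 * self.n_topics_true:
            raise ConfigurationError(
                "vocab_size must be >= 10 * n_topics_true for separability")
        split = np.asarray(self.party_split, dtype=float)
        if split.shape != (3,) or abs(split.sum() - 1.0) > 1e-9 or (split < 0).any():
            raise ConfigurationError(
                "party_split must be 3 nonnegative proportions summing to 1")
        if self.topic_word_concentration <= 0:
            raise ConfigurationError("topic_word_concentration must be positive")
        if self.mixture_concentration <= 0:
            raise ConfigurationError("mixture_concentration must be positive")
        if self.doc_length_mean <= 0:
            raise ConfigurationError("doc_length_mean must be positive")
        if not self.months:
            raise ConfigurationError("months must be nonempty")
        if self.tweets_per_month is not None:
            if len(self.tweets_per_month) != len(self.months):
                raise ConfigurationError(
                    "tweets_per_month must align with months")
            if sum(self.tweets_per_month) != self.n_tweets:
                raise ConfigurationError(
                    "tweets_per_month must sum to n_tweets")
        for party, month_idx in ((p, m) for p in ("D", "R")
                                 for m in range(len(self.months))):
            vec = self.mixture_for(party, month_idx)
            if vec.shape != (self.n_topics_true,):
                raise ConfigurationError(
                    f"party_topic_mixtures[{party}] has wrong length")
            if abs(vec.sum() - 1.0) > 1e-9 or (vec < 0).any():
                raise ConfigurationError(
                    f"party_topic_mixtures[{party}] month {month_idx} "
                    "must be a probability vector summing to 1")

    def mixture_for(self, party: str, month_idx: int) -> np.ndarray:
        """Planted mean topic mixture for one party and month."""
        K = self.n_topics_true
        if party == "I":
            # Independents: midpoint of the two major-party mixtures.
            return 0.5 * (self.mixture_for("D", month_idx)
                          + self.mixture_for("R", month_idx))
        raw = self.party_topic_mixtures.get(party)
        if raw is None:
            return np.full(K, 1.0 / K)
        arr = np.asarray(raw, dtype=float)
        if arr.ndim == 1:
            return arr
        return arr[month_idx]


@dataclass
class GroundTruth:
    """Planted quantities for recovery testing.

    ``theta`` holds the exact per-document mixture used during sampling
    (not re-estimated); ``phi`` the true topic-word distributions;
    ``planted_polarization`` the per-month sum of absolute differences
    between the party mean mixtures, on the 0–200 percent scale.
    """

    theta: np.ndarray            # (n_tweets, K*)
    phi: np.ndarray              # (K*, V)
    vocabulary: list[str]
    mixtures: dict               # {party: (n_months, K*) array}
    months: list[str]
    planted_polarization: dict   # {month: value in [0, 200]}


def planted_polarization(mix_d: np.ndarray, mix_r: np.ndarray) -> float:
    """Sum over topics of |D − R| mean topic representation (0–200 scale)."""
    return float(np.abs(100.0 * mix_d - 100.0 * mix_r).sum())


def _month_bounds(month: str) -> tuple[datetime, datetime]:
    year, mon = (int(p) for p in month.split("-"))
    start = datetime(year, mon, 1, tzinfo=timezone.utc)
    ndays = calendar.monthrange(year, mon)[1]
    return start, start + timedelta(days=ndays)


def generate_corpus(spec: SyntheticCorpusSpec
                    ) -> tuple[list[TweetRecord], GroundTruth]:
    """Generate a corpus and its ground truth.

    Deterministic in ``spec.seed``: identical spec and seed give a
    byte-identical corpus.  Every document is guaranteed at least one
    vaccine-lexicon token (appended when topic sampling produced none, so
    the planted topic structure is not distorted), and document lengths
    are Poisson(doc_length_mean) truncated at a minimum of 3 tokens so
    bigram extraction stays nondegenerate.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    K, V, n = spec.n_topics_true, spec.vocab_size, spec.n_tweets
    n_months = len(spec.months)

    width = len(str(V))
    vocabulary = [f"w{i:0{width}d}" for i in range(V)]
    phi = rng.dirichlet(np.full(V, spec.topic_word_concentration), size=K)

    # Month assignment: explicit volumes or as even as possible.
    if spec.tweets_per_month is not None:
        volumes = list(spec.tweets_per_month)
    else:
        base, rem = divmod(n, n_months)
        volumes = [base + (1 if i < rem else 0) for i in range(n_months)]
    month_of_doc = np.repeat(np.arange(n_months), volumes)

    party_idx = rng.choice(3, size=n, p=np.asarray(spec.party_split, dtype=float))
    parties = np.array(PARTY_ORDER)[party_idx]

    lengths = rng.poisson(spec.doc_length_mean, size=n)
    lengths = np.maximum(lengths, 3)

    # Per-document mixtures, drawn group-wise for speed.
    theta = np.empty((n, K))
    for m in range(n_months):
        for p, pname in enumerate(PARTY_ORDER):
            mask = (month_of_doc == m) & (party_idx == p)
            cnt = int(mask.sum())
            if cnt:
                alpha = spec.mixture_concentration * spec.mixture_for(pname, m)
                # Dirichlet needs strictly positive parameters; planted
                # zeros become a point-mass-like tiny concentration.
                alpha = np.maximum(alpha, 1e-12)
                theta[mask] = rng.dirichlet(alpha, size=cnt)

    # Token topics per document, then words drawn per topic in one batch.
    topic_counts = np.empty((n, K), dtype=np.int64)
    for d in range(n):
        topic_counts[d] = rng.multinomial(lengths[d], theta[d])
    totals = topic_counts.sum(axis=0)
    words_by_topic = [rng.choice(V, size=int(totals[k]), p=phi[k])
                      for k in range(K)]

    retweet_p = np.array([spec.retweet_prob.get(p, 0.0) for p in PARTY_ORDER])
    covid_p = np.array([spec.covid_tag_prob.get(p, 0.0) for p in PARTY_ORDER])
    noncov_p = np.array([spec.noncovid_tag_prob.get(p, 0.0) for p in PARTY_ORDER])
    u = rng.random((n, 3))
    is_retweet = u[:, 0] < retweet_p[party_idx]
    has_covid = u[:, 1] < covid_p[party_idx]
    has_noncovid = u[:, 2] < noncov_p[party_idx]

    # Author pool: ~1 author per 8 tweets per party, at least 2 each.
    n_authors = {p: max(2, int(round((party_idx == i).sum() / 8)))
                 for i, p in enumerate(PARTY_ORDER)}
    author_choice = rng.integers(0, 1 << 30, size=n)

    id_width = len(str(n))
    records: list[TweetRecord] = []
    cursors = np.zeros(K, dtype=np.int64)
    for d in range(n):
        toks: list[str] = []
        for k in range(K):
            c = topic_counts[d, k]
            if c:
                start = cursors[k]
                toks.extend(vocabulary[w]
                            for w in words_by_topic[k][start:start + c])
                cursors[k] += c
        order = rng.permutation(len(toks))
        toks = [toks[i] for i in order]
        toks.append(VACCINE_FILLER)  # abstract words never match the lexicon
        if has_covid[d]:
            toks.append(COVID_FILLER)
        if has_noncovid[d]:
            toks.append(NONCOVID_FILLER)

        m = month_of_doc[d]
        start_ts, end_ts = _month_bounds(spec.months[m])
        ts = start_ts + (end_ts - start_ts) * rng.random()
        ts = ts.replace(microsecond=0)

        p = parties[d]
        author = f"{p}{author_choice[d] % n_authors[p]:04d}"
        text = " ".join(toks)
        records.append(TweetRecord(
            id=f"t{d:0{id_width}d}",
            timestamp=ts,
            author_id=author,
            party=p,
            chamber="state" if (author_choice[d] >> 8) % 4 else "federal",
            is_retweet=bool(is_retweet[d]),
            text=text,
            tokens=normalize(text),
        ))

    mixtures = {p: np.stack([spec.mixture_for(p, m) for m in range(n_months)])
                for p in ("D", "R")}
    planted = {month: planted_polarization(mixtures["D"][m], mixtures["R"][m])
               for m, month in enumerate(spec.months)}
    truth = GroundTruth(theta=theta, phi=phi, vocabulary=vocabulary,
                        mixtures=mixtures, months=list(spec.months),
                        planted_polarization=planted)
    return records, truth


def write_truth(truth: GroundTruth, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({
            "theta": truth.theta.tolist(),
            "phi": truth.phi.tolist(),
            "vocabulary": truth.vocabulary,
            "mixtures": {p: v.tolist() for p, v in truth.mixtures.items()},
            "months": truth.months,
            "planted_polarization": truth.planted_polarization,
        }, fh)


#: Planted party mixtures for the standard recovery benchmark: balanced
#: enough that every topic receives tokens, separated enough that the two
#: parties differ (planted polarization = 90 on the 0-200 scale).
BENCHMARK_MIX_D = (0.40, 0.25, 0.15, 0.10, 0.10)
BENCHMARK_MIX_R = (0.10, 0.10, 0.15, 0.25, 0.40)


def benchmark_spec(seed: int = 42, n_tweets: int = 2000,
                   months: list[str] | None = None) -> SyntheticCorpusSpec:
    """The standard topic-recovery benchmark corpus.

    K* = 5 planted topics over a 500-term vocabulary, 2,000 tweets of
    mean length 15, sparse topics (word concentration 0.05) and sparse
    document mixtures (concentration 0.5) around fixed well-separated
    party means — conditions under which the planted structure is
    recoverable by a correctly implemented sampler.
    """
    return SyntheticCorpusSpec(
        n_tweets=n_tweets, n_topics_true=5, vocab_size=500,
        topic_word_concentration=0.05,
        party_topic_mixtures={"D": list(BENCHMARK_MIX_D),
                              "R": list(BENCHMARK_MIX_R)},
        mixture_concentration=0.5, doc_length_mean=15.0,
        months=months or ["2020-06"], seed=seed)


#: Scaling of the planted partisan gap per month (February–November):
#: polarization dips early in the window, then rises through autumn.
VSHAPE_DELTAS = (1.0, 0.6, 0.3, 0.5, 0.7, 0.85, 1.0, 1.15, 1.3, 1.45)


def vshape_spec(seed: int = 0, tweets_per_month: int = 2000
                ) -> SyntheticCorpusSpec:
    """Corpus spec planting a V-shaped polarization trend.

    Ten calendar months (February–November 2020).  Party mixtures sit at
    ``base ± delta_m * direction`` so the planted polarization is
    ``60 * delta_m`` (range 18–87): it decreases over the first three
    months and increases monotonically afterwards, the trend shape the
    trend-recovery checks must detect.
    """
    base = np.full(5, 0.2)
    direction = np.array([0.1, 0.05, 0.0, -0.05, -0.1])
    months = [f"2020-{m:02d}" for m in range(2, 12)]
    mix_d = [(base + d * direction).tolist() for d in VSHAPE_DELTAS]
    mix_r = [(base - d * direction).tolist() for d in VSHAPE_DELTAS]
    return SyntheticCorpusSpec(
        n_tweets=tweets_per_month * len(months),
        n_topics_true=5, vocab_size=500, topic_word_concentration=0.05,
        party_topic_mixtures={"D": mix_d, "R": mix_r},
        mixture_concentration=0.5, doc_length_mean=15.0, months=months,
        tweets_per_month=[tweets_per_month] * len(months), seed=seed)


# --------------------------------------------------------------------------
# Case-count series for wave segmentation
# --------------------------------------------------------------------------

def generate_case_series(n_days: int, trough_days: list[int],
                         noise_sd: float = 0.0, seed: int = 0,
                         window: int = 7) -> np.ndarray:
    """Daily new-case counts with troughs planted in the moving average.

    With ``noise_sd=0`` the trailing ``window``-day moving average of the
    returned series has interior local minima exactly at ``trough_days``.
    Because a trailing window of width w centred on a symmetric raw-series
    minimum reaches its own minimum (w-1)//2 days later, the raw minima
    are planted that many days earlier than each requested trough.  The
    raw series is piecewise linear — proportional to the distance to the
    nearest raw minimum — so each trough's neighbourhood is symmetric.
    """
    if n_days < 1:
        raise ValueError("n_days must be positive")
    troughs = list(trough_days)
    if any(t < 0 or t >= n_days for t in troughs):
        raise ValueError(f"trough day outside [0, {n_days}): {troughs}")
    if sorted(troughs) != troughs or len(set(troughs)) != len(troughs):
        raise ValueError("trough_days must be strictly increasing")
    shift = (window - 1) // 2
    for i, t in enumerate(troughs):
        if t < window or t > n_days - 1 - window:
            raise ValueError(
                f"trough day {t} too close to the series boundary")
        if i and t - troughs[i - 1] < 2 * window:
            raise ValueError("troughs closer than twice the window")

    days = np.arange(n_days)
    if troughs:
        mins = np.array([t - shift for t in troughs])
        dist = np.min(np.abs(days[:, None] - mins[None, :]), axis=1)
        series = 50.0 + 200.0 * dist
    else:
        series = 50.0 + 10.0 * days  # monotone increasing template

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        series = series + rng.normal(0.0, noise_sd, size=n_days)
    return np.maximum(np.rint(series), 0).astype(np.int64)
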