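"""Differential term usage between parties.

Builds a unigram + bigram document-frequency table over D and R tweets,
applies the 0.1% frequency floor, chi-square tests every retained term
with a Bonferroni-corrected significance cutoff, and prepares the
log-log scatter layout of D vs R term frequencies.  The analysis can be
repeated within pandemic waves.

"Frequency" here is document frequency — the share of a party's tweets
containing the term at least once — because the tweet is the unit of
analysis throughout; a token-share variant is available via ``count_mode``.
Bigrams are formed from adjacent surface tokens within a sentence (they
never cross sentence-final punctuation); hyphenated tokens contribute
their whole form to bigrams while both the whole form and the parts are
indexed as unigrams.  Stopwords are deliberately retained: common words
such as "free" can themselves be partisan signals.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from datetime import datetime
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ingest import TweetRecord, sentence_tokens

logger = logging.getLogger(__name__)

MIN_PARTY_TWEETS = 10


def tweet_terms(record: TweetRecord, ngram_max: int = 2) -> set[str]:
    """Distinct terms (unigrams and space-joined bigrams) of one tweet."""
    sentences = sentence_tokens(record.text) if record.text else []
    if not sentences and record.tokens:
        sentences = [list(record.tokens)]
    terms: set[str] = set()
    for sent in sentences:
        terms.update(sent)
        if ngram_max >= 2:
            # Bigrams over surface tokens: skip the indexed hyphen parts,
            # which directly follow their hyphenated whole form.
            surface = []
            i = 0
            while i < len(sent):
                tok = sent[i]
                surface.append(tok)
                if "-" in tok:
                    i += len([p for p in tok.split("-") if p])
                i += 1
            terms.update(f"{a} {b}" for a, b in zip(surface, surface[1:]))
    return terms


def _token_multiset(record: TweetRecord, ngram_max: int) -> Counter:
    sentences = sentence_tokens(record.text) if record.text else []
    if not sentences and record.tokens:
        sentences = [list(record.tokens)]
    counts: Counter = Counter()
    for sent in sentences:
        counts.update(sent)
        if ngram_max >= 2:
            counts.update(f"{a} {b}" for a, b in zip(sent, sent[1:]))
    return counts


def build_term_table(records: Sequence[TweetRecord], ngram_max: int = 2,
                     floor: float = 0.001, denominator: str = "per_party",
                     count_mode: str = "document") -> pd.DataFrame:
    """Per-party term-frequency table with the frequency floor applied.

    Returns a DataFrame (term, n_D, n_R, prop_D, prop_R) with the total
    number of D and R tweets in ``.attrs["N_D"]`` / ``.attrs["N_R"]``.
    A term counts once per tweet regardless of repetitions.  The floor
    keeps a term if its proportion reaches ``floor`` in either party
    (``denominator="per_party"``, the default) or in the pooled corpus
    (``denominator="pooled"``).
    """
    if denominator not in ("per_party", "pooled"):
        raise ValueError(f"unknown denominator: {denominator!r}")
    if count_mode not in ("document", "token"):
        raise ValueError(f"unknown count_mode: {count_mode!r}")

    by_party = {"D": [], "R": []}
    for rec in records:
        if rec.party in by_party:
            by_party[rec.party].append(rec)
    n_d, n_r = len(by_party["D"]), len(by_party["R"])
    if n_d < MIN_PARTY_TWEETS or n_r < MIN_PARTY_TWEETS:
        raise ValueError(
            f"need >= {MIN_PARTY_TWEETS} tweets per party "
            f"(got D={n_d}, R={n_r}); proportions are unstable below that")

    counts = {"D": Counter(), "R": Counter()}
    denom = {"D": n_d, "R": n_r}
    for party, recs in by_party.items():
        if count_mode == "document":
            for rec in recs:
                counts[party].update(tweet_terms(rec, ngram_max))
        else:
            total = 0
            for rec in recs:
                ms = _token_multiset(rec, ngram_max)
                counts[party].update(ms)
                total += sum(ms.values())
            denom[party] = max(total, 1)

    terms = sorted(set(counts["D"]) | set(counts["R"]))
    n_D = np.array([counts["D"][t] for t in terms], dtype=np.int64)
    n_R = np.array([counts["R"][t] for t in terms], dtype=np.int64)
    prop_D = n_D / denom["D"]
    prop_R = n_R / denom["R"]
    if denominator == "per_party":
        keep = (prop_D >= floor) | (prop_R >= floor)
    else:
        keep = (n_D + n_R) / (denom["D"] + denom["R"]) >= floor

    table = pd.DataFrame({
        "term": np.array(terms, dtype=object)[keep],
        "n_D": n_D[keep],
        "n_R": n_R[keep],
        "prop_D": prop_D[keep],
        "prop_R": prop_R[keep],
    }).reset_index(drop=True)
    table.attrs["N_D"] = n_d
    table.attrs["N_R"] = n_r
    table.attrs["count_mode"] = count_mode
    return table


def test_terms(table: pd.DataFrame, alpha: float = 0.001) -> pd.DataFrame:
    """Chi-square test of party association for every retained term.

    Each term forms a 2x2 contains/not-contains by party table tested
    with the Pearson chi-square (no continuity correction).  The
    Bonferroni family size m is the number of retained terms, so a term
    is significant iff its raw p < alpha/m.  Direction is the party with
    the higher proportion (null on exact ties).  Terms with a degenerate
    table (present in every tweet or absent everywhere) get p = 1.
    """
    m = len(table)
    if m == 0:
        out = table.copy()
        out["chi2"] = out["p"] = np.nan
        out["significant"] = False
        out["direction"] = None
        return out
    N_D, N_R = table.attrs["N_D"], table.attrs["N_R"]
    a = table["n_D"].to_numpy(dtype=float)
    c = table["n_R"].to_numpy(dtype=float)
    b = N_D - a
    d = N_R - c
    n = N_D + N_R
    # Closed form for the 2x2 Pearson statistic, vectorized over terms.
    margins = (a + b) * (c + d) * (a + c) * (b + d)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = n * (a * d - b * c) ** 2 / margins
    degenerate = margins == 0
    chi2 = np.where(degenerate, 0.0, chi2)
    p = stats.chi2.sf(chi2, df=1)
    p = np.where(degenerate, 1.0, p)

    cutoff = alpha / m
    prop_D = table["prop_D"].to_numpy()
    prop_R = table["prop_R"].to_numpy()
    direction = np.where(prop_D > prop_R, "D",
                         np.where(prop_R > prop_D, "R", None))
    out = table.copy()
    out["chi2"] = chi2
    out["p"] = p
    out["significant"] = p < cutoff
    out["direction"] = direction
    out.attrs.update(table.attrs)
    out.attrs["alpha"] = alpha
    out.attrs["family_size"] = m
    return out


def scatter_data(results: pd.DataFrame,
                 pseudo_floor: float = 1e-4) -> pd.DataFrame:
    """Plot-ready rows for the D-vs-R term-frequency scatter.

    Proportions are log10-scaled; zeros map to ``pseudo_floor`` so they
    stay displayable.  A term used equally by both parties falls on the
    diagonal; D-leaning terms above it, R-leaning below.
    """
    out = results[["term", "significant", "direction"]].copy() \
        if len(results) else pd.DataFrame(
            columns=["term", "significant", "direction",
                     "log_prop_D", "log_prop_R"])
    if not len(results):
        return out
    out["log_prop_D"] = np.log10(
        np.maximum(results["prop_D"].to_numpy(), pseudo_floor))
    out["log_prop_R"] = np.log10(
        np.maximum(results["prop_R"].to_numpy(), pseudo_floor))
    return out


def per_wave_analysis(records: Sequence[TweetRecord],
                      wave_boundaries: Sequence[datetime],
                      ngram_max: int = 2, floor: float = 0.001,
                      alpha: float = 0.001) -> dict[int, pd.DataFrame]:
    """Run the term analysis independently within each pandemic wave.

    ``wave_boundaries`` are the interior dates splitting the window into
    waves 1..len+1 (a record belongs to the first wave whose boundary
    exceeds its timestamp).  The floor and the Bonferroni family are
    recomputed per wave.  Waves with fewer than 10 tweets in either
    party are skipped with a warning.
    """
    boundaries = sorted(wave_boundaries)
    waves: dict[int, list[TweetRecord]] = {
        i + 1: [] for i in range(len(boundaries) + 1)}
    for rec in records:
        w = 1 + sum(1 for b in boundaries if rec.timestamp >= b)
        waves[w].append(rec)

    results: dict[int, pd.DataFrame] = {}
    for w, recs in waves.items():
        try:
            table = build_term_table(recs, ngram_max=ngram_max, floor=floor)
        except ValueError as exc:
            logger.warning("wave %d skipped: %s", w, exc)
            continue
        res = test_terms(table, alpha=alpha)
        res["wave"] = w
        results[w] = res
    return results
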