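"""Corpus summaries and party-by-characteristic contingency tests.

Percentages are rounded half-up to one decimal, matching the convention
of printed summary tables.  Chi-square tests are Pearson tests without
continuity correction (a Yates-corrected variant is available via a
switch); tweets from independent or unknown-party legislators are
excluded from all partisan comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ingest import TweetRecord

CHARACTERISTICS = ("is_retweet", "mentions_covid", "mentions_noncovid_disease")


def party_share(count_subset: int, count_total: int) -> float:
    """Percentage 100*subset/total, rounded half-up to 1 decimal."""
    if count_total <= 0:
        raise ValueError("count_total must be positive")
    if count_subset > count_total:
        raise ValueError("count_subset exceeds count_total")
    pct = Decimal(100 * count_subset) / Decimal(count_total)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ContingencyTable2x2:
    """2x2 table: rows party D/R, columns characteristic yes/no."""

    a: int  # D, yes
    b: int  # D, no
    c: int  # R, yes
    d: int  # R, no
    row_labels: tuple[str, str] = ("D", "R")
    col_labels: tuple[str, str] = ("yes", "no")

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be nonnegative")
        if self.total == 0:
            raise ValueError("table total must be positive")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def to_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


def crosstab(records: Iterable[TweetRecord],
             characteristic: str) -> ContingencyTable2x2:
    """Cross-tabulate party (D/R) against one boolean tweet characteristic.

    Independents and unknown-party records are excluded; the cell counts
    partition the remaining records.
    """
    if characteristic not in CHARACTERISTICS:
        raise ValueError(f"unknown characteristic: {characteristic!r}")
    a = b = c = d = 0
    for rec in records:
        if rec.party == "D":
            if getattr(rec, characteristic):
                a += 1
            else:
                b += 1
        elif rec.party == "R":
            if getattr(rec, characteristic):
                c += 1
            else:
                d += 1
    if a + b == 0 or c + d == 0:
        raise ValueError(
            "both parties must be present; filter or regenerate the corpus")
    return ContingencyTable2x2(a, b, c, d,
                               col_labels=(characteristic, f"not {characteristic}"))


def chi2_2x2(table: ContingencyTable2x2,
             correction: bool = False) -> tuple[float, float]:
    """Pearson chi-square test of independence on a 2x2 table (df=1).

    No continuity correction by default; ``correction=True`` enables the
    Yates correction.  Raises if a row or column margin is zero (the test
    is undefined there).
    """
    arr = table.to_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("zero row/column margin: chi-square undefined")
    res = stats.chi2_contingency(arr, correction=correction)
    return float(res.statistic), float(res.pvalue)


def summary_table(records: Sequence[TweetRecord],
                  characteristics: Sequence[str] = CHARACTERISTICS
                  ) -> pd.DataFrame:
    """Per-characteristic partisan summary: %D, nD, %R, nR, chi2, p."""
    rows = []
    for char in characteristics:
        tab = crosstab(records, char)
        stat, p = chi2_2x2(tab)
        rows.append({
            "characteristic": char,
            "pct_D": party_share(tab.a, tab.a + tab.b),
            "n_D": tab.a,
            "pct_R": party_share(tab.c, tab.c + tab.d),
            "n_R": tab.c,
            "chi2": stat,
            "p": p,
        })
    return pd.DataFrame(rows)


def corpus_overview(records: Sequence[TweetRecord]) -> pd.DataFrame:
    """Overall composition: tweets by party, retweet and disease-flag shares."""
    n = len(records)
    rows = [("tweets_total", n, 100.0)]
    for p in ("D", "R", "I"):
        cnt = sum(1 for r in records if r.party == p)
        rows.append((f"party_{p}", cnt, party_share(cnt, n)))
    for char, label in (("is_retweet", "retweets"),
                        ("mentions_covid", "covid_mentions"),
                        ("mentions_noncovid_disease", "noncovid_mentions")):
        cnt = sum(1 for r in records if getattr(r, char))
        rows.append((label, cnt, party_share(cnt, n)))
    return pd.DataFrame(rows, columns=["quantity", "n", "pct"])
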