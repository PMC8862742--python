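"""Topic representation by party, party-difference tests, the monthly
polarization index, and pandemic-wave segmentation.

Mean topic representation for a (party, period) stratum is the mean of
the documents' topic probabilities multiplied by 100%, so a party's
representations sum to 100 across topics.  The polarization index of a
month is the sum over topics of the absolute D−R difference in mean
topic representation; it ranges from 0 (identical topic use) to 200
(disjoint topic use).  Months lacking tweets from either party yield a
missing point, never a silent zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date, datetime
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ingest import TweetRecord

logger = logging.getLogger(__name__)


def mean_topic_representation(theta_rows: np.ndarray) -> np.ndarray:
    """Elementwise mean of θ rows × 100; sums to 100 across topics."""
    theta_rows = np.asarray(theta_rows, dtype=float)
    if theta_rows.ndim == 1:
        theta_rows = theta_rows[None, :]
    if theta_rows.shape[0] == 0:
        raise ValueError("empty stratum has no topic representation")
    return 100.0 * theta_rows.mean(axis=0)


def representation_table(theta: np.ndarray, parties: Sequence[str],
                         periods: Sequence, included_topics:
                         Sequence[int] | None = None) -> pd.DataFrame:
    """Long-format (topic, party, period, value) representation table."""
    theta = np.asarray(theta, dtype=float)
    parties = np.asarray(parties, dtype=object)
    periods = np.asarray(periods, dtype=object)
    topics = (list(included_topics) if included_topics is not None
              else list(range(theta.shape[1])))
    rows = []
    for period in pd.unique(periods):
        for party in ("D", "R"):
            mask = (parties == party) & (periods == period)
            if not mask.any():
                continue
            rep = mean_topic_representation(theta[mask])
            for k in topics:
                rows.append({"topic": k, "party": party, "period": period,
                             "value": rep[k]})
    return pd.DataFrame(rows)


def compare_party_topics(theta: np.ndarray, parties: Sequence[str],
                         alpha: float = 0.001, method: str = "ranksum",
                         months: Sequence | None = None,
                         included_topics: Sequence[int] | None = None
                         ) -> pd.DataFrame:
    """Per-topic test of partisan difference in topic probability.

    ``method="ranksum"`` (default): two-sided Wilcoxon rank-sum
    (Mann-Whitney) test on per-tweet topic probabilities, D vs R.
    ``method="signed_rank_monthly"``: Wilcoxon signed-rank test over the
    paired monthly (D, R) mean representations — a literal-replication
    variant (requires ``months``).  Bonferroni family size is the number
    of included topics; direction is the party with the higher mean.
    """
    theta = np.asarray(theta, dtype=float)
    parties = np.asarray(parties, dtype=object)
    topics = (list(included_topics) if included_topics is not None
              else list(range(theta.shape[1])))
    m = len(topics)
    d_mask = parties == "D"
    r_mask = parties == "R"
    rows = []
    for k in topics:
        if method == "ranksum":
            x, y = theta[d_mask, k], theta[r_mask, k]
            if len(x) < 2 or len(y) < 2:
                logger.warning("topic %d skipped: <2 observations in a party", k)
                continue
            if np.array_equal(np.sort(x), np.sort(y)):
                p = 1.0  # identical samples: no evidence of difference
            else:
                p = float(stats.mannwhitneyu(x, y, alternative="two-sided",
                                             method="auto").pvalue)
            mean_d, mean_r = float(np.mean(x)), float(np.mean(y))
        elif method == "signed_rank_monthly":
            if months is None:
                raise ValueError("signed_rank_monthly requires months")
            months_arr = np.asarray(months, dtype=object)
            pairs = []
            for mo in pd.unique(months_arr):
                dm = d_mask & (months_arr == mo)
                rm = r_mask & (months_arr == mo)
                if dm.any() and rm.any():
                    pairs.append((100 * theta[dm, k].mean(),
                                  100 * theta[rm, k].mean()))
            if len(pairs) < 2:
                logger.warning("topic %d skipped: <2 month pairs", k)
                continue
            d_vals, r_vals = map(np.array, zip(*pairs))
            diff = d_vals - r_vals
            if np.allclose(diff, 0):
                p = 1.0
            else:
                p = float(stats.wilcoxon(d_vals, r_vals).pvalue)
            mean_d, mean_r = float(d_vals.mean()), float(r_vals.mean())
        else:
            raise ValueError(f"unknown method: {method!r}")
        direction = "D" if mean_d > mean_r else ("R" if mean_r > mean_d else None)
        rows.append({"topic": k, "p": p, "significant": p < alpha / m,
                     "direction": direction,
                     "mean_D": mean_d, "mean_R": mean_r})
    out = pd.DataFrame(rows)
    out.attrs["alpha"] = alpha
    out.attrs["family_size"] = m
    return out


# --------------------------------------------------------------------------
# Polarization index
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PolarizationPoint:
    month: str
    value: float       # NaN when a party is missing that month
    n_D: int
    n_R: int


def month_key(ts: datetime) -> str:
    return f"{ts.year:04d}-{ts.month:02d}"


def polarization_series(theta: np.ndarray,
                        records: Sequence[TweetRecord],
                        included_topics: Sequence[int] | None = None
                        ) -> list[PolarizationPoint]:
    """Monthly Σ-of-absolute-differences polarization index.

    ``theta`` rows must align with ``records``.  For each calendar month
    the D and R mean topic representations over ``included_topics`` are
    compared; months where either party is absent produce a NaN-valued
    point (logged).  Points are returned in chronological order.
    """
    theta = np.asarray(theta, dtype=float)
    if len(records) != theta.shape[0]:
        raise ValueError("records and theta rows must align")
    topics = (np.asarray(included_topics, dtype=int)
              if included_topics is not None
              else np.arange(theta.shape[1]))
    months = np.array([month_key(r.timestamp) for r in records], dtype=object)
    parties = np.array([r.party for r in records], dtype=object)

    points = []
    for mo in sorted(set(months)):
        d_mask = (months == mo) & (parties == "D")
        r_mask = (months == mo) & (parties == "R")
        n_d, n_r = int(d_mask.sum()), int(r_mask.sum())
        if n_d == 0 or n_r == 0:
            logger.warning("month %s missing a party (D=%d, R=%d); "
                           "polarization is missing, not zero", mo, n_d, n_r)
            points.append(PolarizationPoint(mo, float("nan"), n_d, n_r))
            continue
        rep_d = mean_topic_representation(theta[d_mask])[topics]
        rep_r = mean_topic_representation(theta[r_mask])[topics]
        points.append(PolarizationPoint(
            mo, float(np.abs(rep_d - rep_r).sum()), n_d, n_r))
    return points


def polarization_frame(points: Iterable[PolarizationPoint]) -> pd.DataFrame:
    return pd.DataFrame([{"month": p.month, "value": p.value,
                          "n_D": p.n_D, "n_R": p.n_R} for p in points])


def polarization_trend_check(points: Sequence[PolarizationPoint]) -> dict:
    """First differences and monotone-run summary of a polarization series.

    Returns the per-month deltas, their sign pattern ("+", "-", "0"),
    and the longest monotone (nondecreasing or nonincreasing) run length,
    over the non-missing points.
    """
    values = [p.value for p in points if not np.isnan(p.value)]
    if len(values) < 3:
        raise ValueError("need >= 3 non-missing points")
    deltas = np.diff(values)
    signs = ["+" if d > 0 else ("-" if d < 0 else "0") for d in deltas]
    longest = run = 1
    for i in range(1, len(deltas)):
        same_dir = (deltas[i] >= 0 and deltas[i - 1] >= 0) or \
                   (deltas[i] <= 0 and deltas[i - 1] <= 0)
        run = run + 1 if same_dir else 1
        longest = max(longest, run)
    return {"deltas": deltas, "sign_pattern": "".join(signs),
            "longest_monotone_run": longest + 1}


def v_shape_recovered(points: Sequence[PolarizationPoint], n_down: int,
                      max_up_violations: int = 1) -> bool:
    """Does a series show the planted V: an initial decline, then a rise?

    True when every one of the first ``n_down`` first differences is
    negative and at most ``max_up_violations`` of the remaining
    differences are non-positive.  The tolerance on the rising phase
    mirrors the qualitative shape being planted — polarization that
    falls early and rises for most (not necessarily all) of the rest of
    the window — rather than demanding every month-to-month step clear
    the Monte-Carlo noise.
    """
    values = [p.value for p in points if not np.isnan(p.value)]
    deltas = np.diff(values)
    if len(deltas) <= n_down:
        raise ValueError("series too short for the requested down-phase")
    down, up = deltas[:n_down], deltas[n_down:]
    return bool((down < 0).all() and (up <= 0).sum() <= max_up_violations)


# --------------------------------------------------------------------------
# Wave segmentation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class WaveBoundaries:
    """Interior boundary positions splitting the window into waves."""

    boundaries: tuple            # day indices or dates, strictly increasing
    n_waves: int
    moving_average: np.ndarray


def segment_waves(case_series, window: int = 7,
                  n_waves: int = 3) -> WaveBoundaries:
    """Wave boundaries at nadirs of the moving average of new cases.

    Computes the trailing ``window``-day moving average, finds interior
    local minima (first index of any plateau), and keeps the
    ``n_waves - 1`` deepest, breaking depth ties by first occurrence.
    If fewer interior nadirs exist, fewer waves are returned with a
    warning.  ``case_series`` may be an array of daily counts or a
    DataFrame with columns (date, new_cases), in which case boundary
    dates rather than indices are returned.
    """
    dates = None
    if isinstance(case_series, pd.DataFrame):
        dates = pd.to_datetime(case_series["date"]).tolist()
        values = case_series["new_cases"].to_numpy(dtype=float)
    else:
        values = np.asarray(case_series, dtype=float)
    if window < 1:
        raise ValueError("window must be >= 1")
    if len(values) < window:
        raise ValueError(f"series shorter than window ({len(values)} < {window})")

    ma = np.convolve(values, np.ones(window) / window, mode="valid")
    # ma[i] averages days i..i+window-1 of the raw series; index it by the
    # trailing day so nadir positions refer to raw-series days.
    offset = window - 1

    candidates = {i for i in range(1, len(ma) - 1)
                  if ma[i] <= ma[i - 1] and ma[i] <= ma[i + 1]}
    # A plateau of equal values counts once, at its first interior index.
    minima = sorted(i for i in candidates
                    if not (i - 1 in candidates and ma[i - 1] == ma[i]))
    if not minima:
        logger.warning("no interior nadir in the moving average; "
                       "returning a single wave")
        return WaveBoundaries((), 1, ma)

    depth_order = sorted(minima, key=lambda i: (ma[i], i))
    chosen = sorted(depth_order[:max(n_waves - 1, 0)])
    if len(chosen) < n_waves - 1:
        logger.warning("only %d interior nadirs found; returning %d waves",
                       len(chosen), len(chosen) + 1)
    idx = tuple(i + offset for i in chosen)
    if dates is not None:
        idx = tuple(dates[i] for i in idx)
    return WaveBoundaries(idx, len(chosen) + 1, ma)
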