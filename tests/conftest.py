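"""Shared fixtures: small hand-built corpora and the recovery benchmark."""

from __future__ import annotations

from datetime import datetime, timezone

import pytest

from polarlex import synthetic, topics
from polarlex.ingest import TweetRecord, apply_flags, normalize


def make_record(i, text="vaccines work", party="D", month=6, day=15,
                is_retweet=False, tokens=None, year=2020):
    rec = TweetRecord(
        id=f"t{i:05d}",
        timestamp=datetime(year, month, day, 12, 0, tzinfo=timezone.utc),
        author_id=f"a{i % 7}",
        party=party,
        chamber="state",
        is_retweet=is_retweet,
        text=text,
        tokens=tokens if tokens is not None else normalize(text),
    )
    return rec


@pytest.fixture(scope="session")
def benchmark_corpus():
    """The standard planted-topic benchmark corpus (K*=5, V=500, D=2000)."""
    spec = synthetic.benchmark_spec(seed=42)
    return synthetic.generate_corpus(spec)


@pytest.fixture(scope="session")
def benchmark_model(benchmark_corpus):
    """Benchmark corpus fitted with the standard sampler settings."""
    records, truth = benchmark_corpus
    params = topics.benchmark_fit_params(seed=43)
    data = topics.build_dtm(records, params)
    model = topics.fit_lda(data, params)
    return model, data, truth


@pytest.fixture(scope="session")
def small_flagged_corpus():
    """120 tweets, both parties, with lexicon flags applied."""
    records = []
    for i in range(120):
        party = "D" if i % 3 else "R"
        text = ("Get your flu shot and stay safe this season"
                if i % 2 else "The covid vaccine is safe and effective")
        records.append(make_record(i, text=text, party=party,
                                   is_retweet=(i % 5 == 0)))
    return apply_flags(records)
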