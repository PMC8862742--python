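"""Tweet ingestion, text normalization, and lexicon-based filtering.

Reads tweet-level records (JSONL or CSV), normalizes tweet text into
tokens, applies a vaccine-term inclusion rule, and tags mentions of
COVID-19 and of non-COVID infectious diseases.  The vaccine filter is the
corpus-defining step: only tweets matching the vaccine lexicon enter any
downstream analysis.
"""

from __future__ import annotations

import csv
import json
import logging
import re
from dataclasses import dataclass, field, replace
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

# --------------------------------------------------------------------------
# Parties and aliases
# --------------------------------------------------------------------------

PARTIES = ("D", "R", "I")

PARTY_ALIASES = {
    "d": "D", "dem": "D", "democrat": "D", "democratic": "D",
    "r": "R", "rep": "R", "republican": "R",
    "i": "I", "ind": "I", "independent": "I",
}

CHAMBER_ALIASES = {
    "state": "state",
    "federal": "federal",
}


def canonical_party(value: object) -> str:
    """Map a raw party label onto {D, R, I, unknown}."""
    if value is None:
        return "unknown"
    key = str(value).strip().lower()
    if not key:
        return "unknown"
    return PARTY_ALIASES.get(key, "unknown")


def canonical_chamber(value: object) -> str:
    if value is None:
        return "unknown"
    key = str(value).strip().lower()
    return CHAMBER_ALIASES.get(key, "unknown")


# --------------------------------------------------------------------------
# Records
# --------------------------------------------------------------------------

@dataclass
class TweetRecord:
    """One tweet with party/chamber/retweet metadata and normalized tokens.

    ``tokens`` is populated by :func:`normalize` (lowercase, URLs and
    @-handles removed).  The three boolean flags are set by
    :func:`apply_flags` and default to False.
    """

    id: str
    timestamp: datetime
    author_id: str
    party: str = "unknown"
    chamber: str = "unknown"
    is_retweet: bool = False
    text: str = ""
    tokens: list[str] = field(default_factory=list)
    is_vaccine: bool = False
    mentions_covid: bool = False
    mentions_noncovid_disease: bool = False

    def copy(self) -> "TweetRecord":
        rec = replace(self)
        rec.tokens = list(self.tokens)
        return rec


# --------------------------------------------------------------------------
# Normalization
# --------------------------------------------------------------------------

_URL_RE = re.compile(r"https?://\S+|www\.\S+")
_HANDLE_RE = re.compile(r"@\w+:?")
_TOKEN_RE = re.compile(r"[a-z0-9_]+(?:-[a-z0-9_]+)*")
_SENTENCE_SPLIT_RE = re.compile(r"[.!?]+(?:\s+|$)")


def _tokenize_fragment(fragment: str) -> list[str]:
    """Tokenize one sentence fragment; hyphenated tokens are kept whole and
    their parts are also indexed immediately after."""
    out: list[str] = []
    for tok in _TOKEN_RE.findall(fragment):
        out.append(tok)
        if "-" in tok:
            out.extend(p for p in tok.split("-") if p)
    return out


def _preclean(text: str) -> str:
    text = text.lower()
    text = _URL_RE.sub(" ", text)
    text = _HANDLE_RE.sub(" ", text)
    text = text.replace("#", " ")
    return text


def normalize(text: str) -> list[str]:
    """Normalize tweet text into an ordered token list.

    Lowercases; strips URLs, @-handles, a leading "rt" retweet marker and
    "#" characters (the hashtag word itself is kept); splits on
    punctuation.  Internal hyphens are preserved ("anti-vaxxers") and the
    hyphen-separated parts are additionally indexed ("anti", "vaxxers").
    """
    if not text:
        return []
    tokens: list[str] = []
    for sent in sentence_tokens(text):
        tokens.extend(sent)
    return tokens


def sentence_tokens(text: str) -> list[list[str]]:
    """Like :func:`normalize` but grouped by sentence, for bigram
    construction that must not cross sentence-final punctuation."""
    if not text:
        return []
    cleaned = _preclean(text)
    sentences: list[list[str]] = []
    first = True
    for fragment in _SENTENCE_SPLIT_RE.split(cleaned):
        toks = _tokenize_fragment(fragment)
        if first and toks and toks[0] == "rt":
            toks = toks[1:]
        if toks:
            sentences.append(toks)
            first = False
    return sentences


# --------------------------------------------------------------------------
# Lexicon
# --------------------------------------------------------------------------

#: Exact vaccine-term list, with parenthetical spellings expanded.
DEFAULT_VACCINE_TERMS_EXACT = frozenset({
    "vaccine", "vaccination", "immunization",
    "vax", "vaxx", "vaxine", "vaxxine",
    "antivax", "antivaxx", "anti-vax", "anti-vaxx",
    "antivaxer", "antivaxxer", "anti-vaxer", "anti-vaxxer",
    "inoculate", "innoculate", "inoculation", "innoculation",
})

#: Default stems for prefix matching; broader than the exact list so that
#: inflected forms ("vaccinated", "vaccines", "anti-vaxxers") match too.
DEFAULT_VACCINE_STEMS = frozenset({
    "vaccin", "vax", "immuniz", "immunis",
    "inoculat", "innoculat", "antivax", "anti-vax",
})

DEFAULT_COVID_TERMS = frozenset({
    "covid", "covid19", "covid-19", "coronavirus", "sars-cov-2", "sarscov2",
})

DEFAULT_NONCOVID_TERMS = frozenset({
    "flu", "influenza", "measles", "mmr", "hpv", "polio", "smallpox",
    "fluseason",
})

_PAREN_RE = re.compile(r"\(([a-z0-9-]+)\)")


def expand_term(term: str) -> set[str]:
    """Expand parenthetical optional spellings: "vax(x)" -> {vax, vaxx}."""
    term = term.lower()
    m = _PAREN_RE.search(term)
    if not m:
        return {term}
    without = term[:m.start()] + term[m.end():]
    with_ = term[:m.start()] + m.group(1) + term[m.end():]
    return expand_term(without) | expand_term(with_)


@dataclass(frozen=True)
class Lexicon:
    """Term sets driving inclusion and disease tagging.

    ``match_mode`` applies to the vaccine inclusion rule: ``stem_prefix``
    (default) matches any token starting with a listed stem, which covers
    inflected forms; ``exact_word`` requires token equality against the
    expanded term list.  The COVID / non-COVID disease sets are explicit
    word lists and are always matched as exact words.
    """

    vaccine_terms: frozenset[str] = DEFAULT_VACCINE_STEMS
    covid_terms: frozenset[str] = DEFAULT_COVID_TERMS
    noncovid_disease_terms: frozenset[str] = DEFAULT_NONCOVID_TERMS
    match_mode: str = "stem_prefix"
    exclusion_terms: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.match_mode not in ("exact_word", "stem_prefix"):
            raise ValueError(f"unknown match_mode: {self.match_mode!r}")
        for name in ("vaccine_terms", "covid_terms", "noncovid_disease_terms"):
            terms = getattr(self, name)
            if not terms:
                raise ValueError(f"{name} must be nonempty")
            object.__setattr__(self, name,
                               frozenset(t.lower() for t in terms))
        overlap = self.covid_terms & self.noncovid_disease_terms
        if overlap:
            raise ValueError(
                f"covid_terms and noncovid_disease_terms overlap: {sorted(overlap)}")

    @classmethod
    def default_exact(cls) -> "Lexicon":
        """Strict-replication lexicon: the printed exact word list."""
        return cls(vaccine_terms=DEFAULT_VACCINE_TERMS_EXACT,
                   match_mode="exact_word")

    @classmethod
    def from_config(cls, cfg: dict) -> "Lexicon":
        kwargs = {}
        for key in ("vaccine_terms", "covid_terms", "noncovid_disease_terms",
                    "exclusion_terms"):
            if key in cfg:
                kwargs[key] = frozenset(str(t).lower() for t in cfg[key])
        if "match_mode" in cfg:
            kwargs["match_mode"] = cfg["match_mode"]
        return cls(**kwargs)


def match_lexicon(tokens: Sequence[str], terms: Iterable[str],
                  mode: str = "exact_word") -> bool:
    """True if any token matches the term set under the given mode.

    ``exact_word``: token equality after expanding parenthetical spellings.
    ``stem_prefix``: any token beginning with a listed stem.  Matching is
    case-insensitive (tokens are normalized lowercase already).
    """
    if not tokens:
        return False
    if mode == "exact_word":
        expanded: set[str] = set()
        for t in terms:
            expanded |= expand_term(t)
        return any(tok in expanded for tok in tokens)
    if mode == "stem_prefix":
        stems = [t.lower() for t in terms]
        return any(tok.startswith(stem) for tok in tokens for stem in stems)
    raise ValueError(f"unknown match mode: {mode!r}")


def apply_flags(records: Iterable[TweetRecord],
                lexicon: Lexicon | None = None) -> list[TweetRecord]:
    """Set is_vaccine / mentions_covid / mentions_noncovid_disease flags.

    The three flags are independent; a tweet mentioning both "flu" and
    "covid" gets both disease flags.  Records without tokens are
    normalized first.
    """
    lexicon = lexicon or Lexicon()
    out = []
    for rec in records:
        if not rec.tokens and rec.text:
            rec.tokens = normalize(rec.text)
        rec.is_vaccine = match_lexicon(rec.tokens, lexicon.vaccine_terms,
                                       lexicon.match_mode)
        if lexicon.exclusion_terms and match_lexicon(
                rec.tokens, lexicon.exclusion_terms, "exact_word"):
            rec.is_vaccine = False
        rec.mentions_covid = match_lexicon(rec.tokens, lexicon.covid_terms,
                                           "exact_word")
        rec.mentions_noncovid_disease = match_lexicon(
            rec.tokens, lexicon.noncovid_disease_terms, "exact_word")
        out.append(rec)
    return out


def filter_vaccine(records: Iterable[TweetRecord]) -> list[TweetRecord]:
    """Keep records whose is_vaccine flag is set (idempotent)."""
    return [r for r in records if r.is_vaccine]


# --------------------------------------------------------------------------
# Loading
# --------------------------------------------------------------------------

REQUIRED_COLUMNS = ("id", "timestamp", "author_id", "party", "chamber",
                    "is_retweet", "text")


class SchemaError(ValueError):
    pass


def _parse_timestamp(value: object) -> datetime:
    if isinstance(value, datetime):
        ts = value
    else:
        ts = datetime.fromisoformat(str(value).replace("Z", "+00:00"))
    if ts.tzinfo is None:
        ts = ts.replace(tzinfo=timezone.utc)
    return ts.astimezone(timezone.utc)


def _parse_bool(value: object) -> bool:
    if isinstance(value, bool):
        return value
    return str(value).strip().lower() in ("1", "true", "t", "yes")


def _record_from_row(row: dict, warn_parties: set[str]) -> TweetRecord:
    party = canonical_party(row.get("party"))
    if party == "unknown" and str(row.get("party") or "").strip():
        raw = str(row["party"])
        if raw not in warn_parties:
            warn_parties.add(raw)
            logger.warning("unrecognized party %r mapped to 'unknown'", raw)
    text = str(row.get("text") or "")
    return TweetRecord(
        id=str(row["id"]),
        timestamp=_parse_timestamp(row["timestamp"]),
        author_id=str(row.get("author_id") or ""),
        party=party,
        chamber=canonical_chamber(row.get("chamber")),
        is_retweet=_parse_bool(row.get("is_retweet")),
        text=text,
        tokens=normalize(text),
    )


def load_tweets(path: str | Path, format: str | None = None) -> list[TweetRecord]:
    """Load tweet records from a JSONL or CSV file.

    The format is inferred from the extension unless given.  Missing
    required columns raise :class:`SchemaError` listing the missing names;
    duplicate ids raise ValueError.  Unparseable party/chamber values map
    to "unknown" with a logged warning.
    """
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "jsonl"
    if format not in ("jsonl", "csv"):
        raise ValueError(f"unknown format: {format!r}")

    rows: list[dict]
    if format == "jsonl":
        rows = []
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if line:
                    rows.append(json.loads(line))
    else:
        with open(path, newline="", encoding="utf-8") as fh:
            rows = list(csv.DictReader(fh))

    if rows:
        missing = [c for c in REQUIRED_COLUMNS if c not in rows[0]]
        if missing:
            raise SchemaError(f"missing required columns: {missing}")

    warn_parties: set[str] = set()
    records = [_record_from_row(row, warn_parties) for row in rows]

    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"duplicate tweet id: {rec.id!r}")
        seen.add(rec.id)
    logger.info("loaded %d tweet records from %s", len(records), path)
    return records


def write_tweets(records: Iterable[TweetRecord], path: str | Path) -> None:
    """Write records as JSONL (one object per line, stable key order)."""
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(json.dumps({
                "id": rec.id,
                "timestamp": rec.timestamp.isoformat(),
                "author_id": rec.author_id,
                "party": rec.party,
                "chamber": rec.chamber,
                "is_retweet": rec.is_retweet,
                "text": rec.text,
            }, sort_keys=False) + "\n")


def filter_window(records: Iterable[TweetRecord], start: datetime,
                  end: datetime) -> list[TweetRecord]:
    """Keep records with start <= timestamp <= end (inclusive both ends, UTC)."""
    if start.tzinfo is None:
        start = start.replace(tzinfo=timezone.utc)
    if end.tzinfo is None:
        end = end.replace(tzinfo=timezone.utc)
    if start > end:
        raise ValueError(f"start {start} after end {end}")
    return [r for r in records if start <= r.timestamp <= end]
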