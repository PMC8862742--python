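"""End-to-end pipeline: filter → descriptive → terms → topics → metrics.

A run is driven by a :class:`RunConfig` (loadable from YAML/JSON); all
randomness flows from a single root seed split per stage, and a manifest
records the config hash, seeds, row counts, and a checksum of every
artifact so a rerun with the same config can be verified byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, time, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import descriptive, ingest, metrics, terms, topics
from .ingest import Lexicon, TweetRecord

logger = logging.getLogger(__name__)

STUDY_START = "2020-02-01"
STUDY_END = "2020-12-11"


@dataclass
class RunConfig:
    """Configuration of one full pipeline run."""

    corpus_path: str
    out_dir: str
    lexicon_path: str | None = None
    case_series_path: str | None = None
    window_start: str = STUDY_START
    window_end: str = STUDY_END
    n_topics: int = 25
    lda_alpha: float | None = None
    lda_beta: float = 0.01
    lda_iterations: int = 500
    lda_burn_in: int = 250
    included_topics: list[int] | None = None
    term_alpha: float = 0.001
    topic_alpha: float = 0.001
    term_floor: float = 0.001
    match_mode: str = "stem_prefix"
    frequency_denominator: str = "per_party"
    test_variant: str = "ranksum"
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        import yaml
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def validate(self) -> None:
        for name in ("corpus_path", "lexicon_path", "case_series_path"):
            value = getattr(self, name)
            if value is not None and not Path(value).exists():
                raise FileNotFoundError(f"{name}: {value} does not exist")
        datetime.fromisoformat(self.window_start)
        datetime.fromisoformat(self.window_end)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _window_bounds(cfg: RunConfig) -> tuple[datetime, datetime]:
    start = datetime.fromisoformat(cfg.window_start)
    end = datetime.fromisoformat(cfg.window_end)
    if end.time() == time(0, 0):
        end = datetime.combine(end.date(), time(23, 59, 59, 999999))
    return (start.replace(tzinfo=timezone.utc),
            end.replace(tzinfo=timezone.utc))


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in order and write artifacts plus a manifest.

    Stage errors abort the run with the stage name; artifacts written up
    to that point are preserved alongside the log.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": dataclasses.asdict(config),
                      "config_hash": config.config_hash(),
                      "seed": config.seed, "stages": {}, "artifacts": {}}
    stage = "filter"
    try:
        lexicon = (Lexicon.from_config(_load_yaml(config.lexicon_path))
                   if config.lexicon_path else Lexicon(match_mode=config.match_mode))
        records = ingest.load_tweets(config.corpus_path)
        records = ingest.apply_flags(records, lexicon)
        start, end = _window_bounds(config)
        records = ingest.filter_window(records, start, end)
        records = ingest.filter_vaccine(records)
        if not records:
            raise ValueError("no records survived filtering")
        ingest.write_tweets(records, out / "filtered.jsonl")
        flag_summary = pd.DataFrame({
            "flag": ["is_vaccine", "mentions_covid", "mentions_noncovid_disease"],
            "n": [sum(getattr(r, f) for r in records)
                  for f in ("is_vaccine", "mentions_covid",
                            "mentions_noncovid_disease")],
        })
        flag_summary.to_csv(out / "flag_summary.tsv", sep="\t", index=False)
        manifest["stages"][stage] = {"n_records": len(records)}

        stage = "descriptive"
        overview = descriptive.corpus_overview(records)
        overview.to_csv(out / "corpus_overview.csv", index=False)
        summary = descriptive.summary_table(records)
        summary.to_csv(out / "descriptive_summary.csv", index=False)
        manifest["stages"][stage] = {"n_characteristics": len(summary)}

        stage = "terms"
        table = terms.build_term_table(
            records, floor=config.term_floor,
            denominator=config.frequency_denominator)
        term_results = terms.test_terms(table, alpha=config.term_alpha)
        term_results.to_csv(out / "term_tests.csv", index=False)
        manifest["stages"][stage] = {
            "n_terms": len(term_results),
            "n_significant": int(term_results["significant"].sum())}

        wave_bounds = None
        if config.case_series_path:
            stage = "waves"
            case_df = pd.read_csv(config.case_series_path)
            waves = metrics.segment_waves(case_df)
            wave_bounds = [pd.Timestamp(b, tz="UTC") for b in waves.boundaries]
            per_wave = terms.per_wave_analysis(records, wave_bounds,
                                               floor=config.term_floor,
                                               alpha=config.term_alpha)
            for w, res in per_wave.items():
                res.to_csv(out / f"term_tests_wave{w}.csv", index=False)
            manifest["stages"][stage] = {
                "n_waves": waves.n_waves,
                "boundaries": [str(b.date()) for b in wave_bounds]}

        stage = "topics"
        params = topics.TopicModelParams(
            K=config.n_topics, alpha=config.lda_alpha, beta=config.lda_beta,
            n_iterations=config.lda_iterations, burn_in=config.lda_burn_in,
            seed=config.seed + 1)
        data = topics.build_dtm(records, params)
        model = topics.fit_lda(data, params)
        model.coherence = topics.coherence_score(model, data)
        _write_model(model, out)
        manifest["stages"][stage] = {
            "K": model.K, "vocabulary": data.n_terms,
            "n_documents": data.n_docs,
            "mean_coherence": float(np.mean(model.coherence))}

        stage = "metrics"
        by_id = {r.id: r for r in records}
        kept = [by_id[i] for i in model.doc_ids]
        included = config.included_topics
        rep = metrics.representation_table(
            model.theta, [r.party for r in kept],
            [metrics.month_key(r.timestamp) for r in kept],
            included_topics=included)
        rep.to_csv(out / "topic_representation.csv", index=False)
        comp = metrics.compare_party_topics(
            model.theta, [r.party for r in kept], alpha=config.topic_alpha,
            method=config.test_variant,
            months=[metrics.month_key(r.timestamp) for r in kept],
            included_topics=included)
        comp.to_csv(out / "topic_party_tests.csv", index=False)
        points = metrics.polarization_series(model.theta, kept,
                                             included_topics=included)
        metrics.polarization_frame(points).to_csv(
            out / "polarization.csv", index=False)
        topic_summary = pd.DataFrame([{
            "topic": k,
            "top_words": " ".join(topics.top_words(model, k, 10)),
            "rep_D": comp.loc[comp["topic"] == k, "mean_D"].squeeze() * 100
            if (comp["topic"] == k).any() else np.nan,
            "rep_R": comp.loc[comp["topic"] == k, "mean_R"].squeeze() * 100
            if (comp["topic"] == k).any() else np.nan,
            "significant": bool(comp.loc[comp["topic"] == k,
                                         "significant"].squeeze())
            if (comp["topic"] == k).any() else False,
        } for k in (included or range(model.K))])
        topic_summary.to_csv(out / "topic_summary.csv", index=False)
        manifest["stages"][stage] = {
            "n_polarization_points": len(points),
            "n_significant_topics": int(comp["significant"].sum())}
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        logger.error("pipeline aborted in stage %r: %s", stage, exc)
        raise

    for path in sorted(out.iterdir()):
        if path.is_file() and path.name != "manifest.json":
            manifest["artifacts"][path.name] = _checksum(path)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _load_yaml(path: str | Path) -> dict:
    import yaml
    with open(path, encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def _write_model(model: topics.TopicModel, out: Path) -> None:
    pd.Series(model.vocabulary).to_csv(out / "vocabulary.tsv", sep="\t",
                                       index=False, header=["term"])
    np.savetxt(out / "phi.csv", model.phi, delimiter=",")
    np.savetxt(out / "theta.csv", model.theta, delimiter=",")
    diag = {"K": model.K,
            "alpha": model.params.effective_alpha,
            "beta": model.params.beta,
            "n_iterations": model.params.n_iterations,
            "burn_in": model.params.burn_in,
            "seed": model.params.seed,
            "log_likelihood_trace": model.log_likelihood_trace.tolist(),
            "coherence": (model.coherence.tolist()
                          if model.coherence is not None else None)}
    (out / "model_diagnostics.json").write_text(json.dumps(diag))
    (out / "doc_ids.txt").write_text("\n".join(model.doc_ids) + "\n")


# --------------------------------------------------------------------------
# Report rendering
# --------------------------------------------------------------------------

def render_report(run_dir: str | Path, filename: str = "report.md") -> Path:
    """Assemble a human-readable markdown summary from run artifacts.

    Sections with missing artifacts are skipped with a notice.  A
    polarization line plot is written alongside when matplotlib can
    render it.
    """
    run_dir = Path(run_dir)
    parts: list[str] = ["# Partisan vaccine-discourse run report\n"]

    def md(df: pd.DataFrame) -> str:
        try:
            return df.to_markdown(index=False)
        except ImportError:       # tabulate unavailable
            return "```\n" + df.to_string(index=False) + "\n```"

    def section(title: str, fname: str, renderer) -> None:
        parts.append(f"## {title}\n")
        path = run_dir / fname
        if not path.exists():
            parts.append(f"_Artifact `{fname}` missing; section skipped._\n")
            return
        parts.append(renderer(path))

    def overview(path: Path) -> str:
        return md(pd.read_csv(path)) + "\n"

    def term_section(path: Path) -> str:
        res = pd.read_csv(path)
        sig = res[res["significant"] == True]  # noqa: E712
        blocks = []
        for party in ("D", "R"):
            top = (sig[sig["direction"] == party]
                   .sort_values("chi2", ascending=False).head(20))
            blocks.append(f"**Top {party}-leaning terms**\n\n"
                          + md(top[["term", "prop_D", "prop_R", "p"]]))
        return "\n\n".join(blocks) + "\n"

    def topic_section(path: Path) -> str:
        return md(pd.read_csv(path)) + "\n"

    def polarization_section(path: Path) -> str:
        df = pd.read_csv(path)
        png = run_dir / "polarization.png"
        try:
            import matplotlib
            matplotlib.use("Agg")
            import matplotlib.pyplot as plt
            fig, ax = plt.subplots(figsize=(7, 3.5))
            ax.plot(df["month"], df["value"], marker="o")
            ax.set_xlabel("month")
            ax.set_ylabel("polarization (sum |D − R| representation)")
            ax.set_ylim(bottom=0)
            fig.autofmt_xdate()
            fig.tight_layout()
            fig.savefig(png, dpi=100)
            plt.close(fig)
            note = f"\n![polarization]({png.name})\n"
        except Exception:      # plotting is best-effort
            note = ""
        return md(df) + "\n" + note

    section("Corpus summary", "corpus_overview.csv", overview)
    section("Party-by-characteristic tests", "descriptive_summary.csv", overview)
    section("Partisan terms", "term_tests.csv", term_section)
    section("Topics", "topic_summary.csv", topic_section)
    section("Polarization by month", "polarization.csv", polarization_section)

    out_path = run_dir / filename
    out_path.write_text("\n".join(parts))
    return out_path
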