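"""Configuration-driven pipeline: screen → match → network → topics → report.

:func:`run_pipeline` chains every audit stage over a corpus, a disclosure
list and a survey table, writing each stage's artifacts (ledger, match
table, coverage report, graph exports, topic summary) into an output
directory.  Every JSON artifact embeds a provenance header (config hash and
seed) and two runs with identical config and inputs produce identical
artifacts.  :func:`render_reports` folds an artifact directory into one
human-readable markdown summary.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import matching, names, network, screening, topics
from .records import (CorpusError, read_disclosure_list, read_records,
                      read_survey_outcomes, read_entity_dictionary,
                      write_records)

__all__ = ["PipelineConfig", "run_pipeline", "render_reports"]

log = logging.getLogger("fundingaudit")


@dataclass
class PipelineConfig:
    corpus_path: str
    disclosure_path: str | None = None
    survey_path: str | None = None
    entity_dictionary_path: str | None = None
    out_dir: str = "audit_out"
    corpus_dialect: str = "jsonl"
    needle: str = "cola"
    window: tuple[tuple[int, int], tuple[int, int]] = screening.DEFAULT_WINDOW
    match_auto_accept: float = 0.90
    match_review_low: float = 0.80
    promote_review: bool = False
    topic_k: int = 20
    topic_iterations: int = 2000
    topic_burn_in: int = 500
    #: community detection is skipped on components larger than this many
    #: edges (divisive edge-betweenness is cubic-ish; huge components are
    #: reported as single communities)
    community_max_edges: int = 2000
    seed: int = 0
    stages: tuple[str, ...] = ("screen", "match", "network", "topics")

    def validate(self) -> None:
        if not Path(self.corpus_path).exists():
            raise CorpusError(f"corpus not found: {self.corpus_path}")
        if "match" in self.stages:
            if self.disclosure_path is None:
                raise CorpusError("matching enabled but no disclosure list given")
            if not Path(self.disclosure_path).exists():
                raise CorpusError(
                    f"disclosure list not found: {self.disclosure_path}")
        if self.survey_path is not None and not Path(self.survey_path).exists():
            raise CorpusError(f"survey table not found: {self.survey_path}")
        if (self.entity_dictionary_path is not None
                and not Path(self.entity_dictionary_path).exists()):
            raise CorpusError(
                f"entity dictionary not found: {self.entity_dictionary_path}")

    def content_hash(self) -> str:
        # hash the analysis parameters, not where the artifacts land
        payload = {k: v for k, v in self.__dict__.items() if k != "out_dir"}
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with Path(path).open(encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if "window" in data:
            (y0, m0), (y1, m1) = data["window"]
            data["window"] = ((int(y0), int(m0)), (int(y1), int(m1)))
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(**data)


def _provenance(config: PipelineConfig) -> dict:
    return {"config_hash": config.content_hash(), "seed": config.seed}


def _dump_json(obj, path: Path, config: PipelineConfig) -> None:
    payload = {"_provenance": _provenance(config)}
    payload.update(obj)
    path.write_text(json.dumps(payload, indent=2, default=str),
                    encoding="utf-8")


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the configured stages; returns the artifact directory.

    Raises :class:`CorpusError` on invalid configuration before any compute;
    a failing stage aborts with the stage named in the exception.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)

    result = read_records(config.corpus_path, config.corpus_dialect)
    if result.errors:
        log.warning("%d malformed corpus rows rejected", len(result.errors))
        (out / "read_errors.json").write_text(json.dumps(
            [e.__dict__ for e in result.errors], indent=2), encoding="utf-8")
    records = result.records
    if config.entity_dictionary_path:
        dictionary = read_entity_dictionary(config.entity_dictionary_path)
    else:
        from .synth import default_entity_dictionary

        dictionary = default_entity_dictionary()

    stage = "screen"
    try:
        ledger = screening.PrismaLedger()
        prefiltered, pre_dec = screening.prefilter_by_substring(
            records, config.needle)
        ledger.add_stage("substring_prefilter", pre_dec)
        screened, scr_dec, mention_map = screening.screen_corpus(
            prefiltered, dictionary)
        ledger.add_stage("direct_funding_screen", scr_dec)
        sample1 = screening.build_sample1(prefiltered, scr_dec)
        sample2, s2_dec = screening.build_sample2(sample1, mention_map)
        ledger.add_stage("brand_eligibility", s2_dec)
        cohort = screening.build_transparency_cohort(
            sample1, mention_map, config.window)
        ledger.add_stage("cohort_eligibility", cohort.decisions)
        screening.export_ledger(ledger, out, _provenance(config))
        write_records(sample1, out / "sample1.jsonl")
        write_records(sample2, out / "sample2.jsonl")
        write_records(cohort.records, out / "cohort.jsonl")
        clusters, assignment = names.cluster_records(cohort.records)
        _dump_json({"n_sample1": len(sample1), "n_sample2": len(sample2),
                    "n_cohort_records": len(cohort.records),
                    "n_cohort_authors": len(clusters)},
                   out / "screen_summary.json", config)
        if "match" not in config.stages:
            return out

        stage = "match"
        disclosure = read_disclosure_list(config.disclosure_path)
        mconfig = matching.MatchConfig(config.match_auto_accept,
                                       config.match_review_low,
                                       config.promote_review)
        results = matching.match_author_lists(clusters, disclosure, mconfig)
        coverage = matching.coverage_metrics(results, clusters, disclosure,
                                             mconfig)
        remaining, remaining_clusters = matching.remove_matched_publications(
            cohort.records, results, clusters, assignment, mconfig)
        coverage.unmatched_author_articles = (len(remaining_clusters),
                                              len(remaining))
        import pandas as pd

        pd.DataFrame([{
            "author_key": r.author_key, "disclosure_name": r.disclosure_name,
            "match_type": r.match_type, "score": r.score,
            "review_status": r.review_status} for r in results]).to_csv(
                out / "matches.csv", index=False)
        _dump_json({
            "n_cohort_authors": coverage.n_cohort_authors,
            "n_disclosure_names": coverage.n_disclosure_names,
            "n_matched": coverage.n_matched,
            "pct_of_disclosure": coverage.pct_of_disclosure,
            "pct_of_cohort": coverage.pct_of_cohort,
            "n_unmatched_disclosure": len(coverage.unmatched_disclosure_names),
            "unmatched_authors": len(remaining_clusters),
            "unmatched_articles": len(remaining),
        }, out / "coverage.json", config)
        write_records(remaining, out / "remaining.jsonl")
        if config.survey_path:
            outcomes = read_survey_outcomes(config.survey_path)
            tally = matching.survey_tally(outcomes)
            adj_clusters, adj_records, problems = \
                matching.apply_survey_adjustments(
                    remaining, remaining_clusters, outcomes, assignment,
                    clusters)
            _dump_json({"tally": tally,
                        "adjusted_authors": len(adj_clusters),
                        "adjusted_articles": len(adj_records),
                        "problems": problems},
                       out / "survey.json", config)
        if "network" not in config.stages:
            return out

        stage = "network"
        matched_idx = {r.cluster_index
                       for r in matching.accepted_matches(results, mconfig)}
        s1_clusters, s1_assign = names.cluster_records(sample1)
        s2_cluster_set = {s1_assign[(rec.record_id, i)]
                          for rec in sample2 for i in range(len(rec.authors))}
        matched_keys = {clusters[i].canonical_key for i in matched_idx}
        status = {}
        for ci, cl in enumerate(s1_clusters):
            if cl.canonical_key in matched_keys:
                status[ci] = "on_list"
            elif ci in s2_cluster_set:
                status[ci] = "unlisted_participating"
            else:
                status[ci] = "unlisted_subsidiary"
        graph = network.build_coauthor_graph(sample1, s1_assign, status)
        stats = network.graph_stats(graph)
        partition = _communities_by_component(graph, config)
        stats["n_communities"] = len(set(partition.assignment.values()))
        stats["modularity"] = partition.quality
        network.export_graph(graph, out / "coauthorship.graphml", partition)
        network.export_graph(graph, out / "coauthorship_edges.tsv", partition,
                             fmt="edgelist")
        pd.DataFrame([
            {"node": n, "community": c,
             "degree": network.degree_centrality(graph)[n]}
            for n, c in sorted(partition.assignment.items(),
                               key=lambda kv: str(kv[0]))]).to_csv(
                out / "communities.csv", index=False)
        _dump_json(stats, out / "network_stats.json", config)
        if "topics" not in config.stages:
            return out

        stage = "topics"
        tokens, vocab, doc_ids = topics.preprocess_abstracts(sample2)
        model = topics.fit_topic_model(
            tokens, k=config.topic_k, n_iter=config.topic_iterations,
            burn_in=config.topic_burn_in, seed=config.seed,
            vocabulary=vocab, doc_ids=doc_ids)
        assignments = topics.dominant_topic_assignment(model)
        summary = topics.topic_summary(model, assignments)
        summary.to_frame().to_csv(out / "topic_summary.csv", index=False)
        pd.DataFrame({"doc_id": model.doc_ids,
                      **{f"topic_{k}": model.doc_topic[:, k]
                         for k in range(model.k)}}).to_csv(
            out / "doc_topics.csv", index=False)
        _dump_json({"k": model.k, "n_documents": len(model.doc_ids),
                    "shares_pct": summary.shares_pct,
                    "mean_ratio": summary.mean_ratio,
                    "top_words": {t: [w for w, _ in ws]
                                  for t, ws in summary.top_words.items()}},
                   out / "topics.json", config)
    except CorpusError as exc:
        raise CorpusError(f"pipeline failed in stage {stage!r}: {exc}") from exc
    return out


def _communities_by_component(graph, config: PipelineConfig
                              ) -> network.CommunityPartition:
    """Girvan–Newman per connected component, skipping oversized ones."""
    import networkx as nx

    assignment = {}
    next_id = 0
    quality_graphs = []
    for comp in sorted(nx.connected_components(graph),
                       key=lambda c: sorted(str(n) for n in c)[0]):
        sub = graph.subgraph(comp)
        if sub.number_of_edges() == 0 or \
                sub.number_of_edges() > config.community_max_edges:
            for n in sorted(comp, key=str):
                assignment[n] = next_id
            next_id += 1
            continue
        part = network.girvan_newman_partition(sub)
        remap = {}
        for n, c in part.assignment.items():
            if c not in remap:
                remap[c] = next_id
                next_id += 1
            assignment[n] = remap[c]
    quality = network._modularity(graph, assignment) if graph.number_of_edges() \
        else 0.0
    return network.CommunityPartition(assignment, quality, [])


def render_reports(artifact_dir: str | Path) -> str:
    """Compose one markdown summary from a pipeline artifact directory.

    Missing artifacts skip their section with a warning line; the function
    never raises for an incomplete directory.
    """
    art = Path(artifact_dir)
    lines = ["# Funding-transparency audit summary", ""]

    def load(name: str):
        p = art / name
        if not p.exists():
            lines.append(f"_(section skipped: {name} not found)_")
            lines.append("")
            return None
        return json.loads(p.read_text(encoding="utf-8"))

    lines.append("## Screening flow")
    ledger = load("prisma_ledger.json")
    if ledger:
        for st in ledger["stages"]:
            reasons = ", ".join(f"{k}={v}" for k, v in
                                sorted(st["reasons"].items())) or "none"
            lines.append(f"- {st['stage']}: {st['input']} -> {st['output']} "
                         f"({st['excluded']} excluded; {reasons})")
        lines.append("")

    lines.append("## Disclosure coverage")
    cov = load("coverage.json")
    if cov:
        lines.append(
            f"- {cov['n_matched']} of {cov['n_cohort_authors']} cohort "
            f"authors matched to the {cov['n_disclosure_names']}-name "
            f"disclosure list ({cov['pct_of_cohort']}% of cohort, "
            f"{cov['pct_of_disclosure']}% of list)")
        lines.append(
            f"- unmatched disclosure names: {cov['n_unmatched_disclosure']}")
        lines.append(
            f"- after removing matched-author publications: "
            f"{cov['unmatched_authors']} authors on "
            f"{cov['unmatched_articles']} articles")
        lines.append("")

    lines.append("## Survey")
    surv = load("survey.json")
    if surv:
        for cat, row in surv["tally"].items():
            if cat != "total":
                lines.append(f"- {cat}: {row['count']} ({row['pct']}%)")
        lines.append(f"- adjusted set: {surv['adjusted_authors']} authors on "
                     f"{surv['adjusted_articles']} articles")
        lines.append("")

    lines.append("## Co-authorship network")
    net = load("network_stats.json")
    if net:
        lines.append(f"- {net['n_nodes']} authors, {net['n_edges']} ties "
                     f"(total weight {net['total_edge_weight']:.0f}), "
                     f"{net['n_components']} components")
        lines.append(f"- {net['n_communities']} communities, modularity "
                     f"{net['modularity']:.3f}")
        lines.append("")

    lines.append("## Topics")
    top = load("topics.json")
    if top:
        shares = top["shares_pct"]
        for t in sorted(shares, key=lambda x: -shares[x]):
            words = " ".join(top["top_words"][str(t)][:7]
                             if str(t) in top["top_words"]
                             else top["top_words"][t][:7])
            lines.append(f"- topic {t}: {shares[t]}% of documents; top stems: "
                         f"{words}")
        lines.append("")

    text = "\n".join(lines)
    (art / "report.md").write_text(text, encoding="utf-8")
    return text
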