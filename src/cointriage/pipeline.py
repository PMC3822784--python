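"""End-to-end orchestration: corpus → tagging → pairs → network → ranking → evaluation.

Each run resolves a :class:`RunConfig`, executes the stages in order per
query group, and writes the full artifact set into the output directory:

* ``features.csv`` — per-article pair counts and z-scores;
* ``edges.tsv`` / ``network.graphml`` — the co-occurrence network;
* ``centrality.csv`` — betweenness and PageRank per article;
* ``ranked.tsv`` — the combined ranking (rank, doc_id, score, label);
* ``feature_matrix.csv`` — Table-style classifier input;
* ``eval.json`` — MAP / per-query AP / P@k (when gold labels exist);
* ``manifest.json`` — the resolved config, package version and seed.

Stages communicate only through these documented formats, so each stage is
independently runnable (see the ``coin`` CLI subcommands) and external NER
output can be substituted by supplying a pre-tagged corpus.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Optional

from . import __version__
from .cooccur import article_features, write_feature_csv, zscore_normalize
from .corpus import Corpus, read_corpus, split_document, write_ranked_tsv
from .evaluation import DEFAULT_K_SET, evaluate
from .network import (
    betweenness,
    build_network,
    pagerank,
    write_centrality_csv,
    write_edgelist_tsv,
    write_graphml,
)
from .ranking import CoinConfig, RankedList, coin_index, export_features, rank_articles, write_feature_matrix
from .tagger import Lexicon, read_lexicon, tag_document

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Resolved settings of one pipeline run."""

    corpus_path: str
    out_dir: str
    gene_lexicon: Optional[str] = None
    chemical_lexicon: Optional[str] = None
    disease_lexicon: Optional[str] = None
    corpus_format: str = "jsonl"
    grouping: str = "per_query"
    include_title: bool = True
    edge_rule: str = "shared_pair"
    coin: CoinConfig = field(default_factory=CoinConfig)
    k_set: tuple[int, ...] = DEFAULT_K_SET
    seed: Optional[int] = None
    log_level: str = "INFO"

    def lexicon_paths(self) -> dict[str, Optional[str]]:
        return {
            "gene": self.gene_lexicon,
            "chemical": self.chemical_lexicon,
            "disease": self.disease_lexicon,
        }

    def validate(self) -> None:
        paths = [self.corpus_path] + [p for p in self.lexicon_paths().values() if p]
        for p in paths:
            if not os.path.exists(p):
                raise FileNotFoundError(f"configured path does not exist: {p}")


class PipelineError(RuntimeError):
    """A stage failure, wrapped with the stage name and context."""

    def __init__(self, stage: str, context: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed ({context}): {cause}")


def _load_lexicons(cfg: RunConfig) -> list[Lexicon]:
    lexicons = []
    for cls, path in cfg.lexicon_paths().items():
        if path:
            lexicons.append(read_lexicon(path, cls))
    return lexicons


def ensure_tagged(corpus: Corpus, lexicons: list[Lexicon], include_title: bool = True) -> Corpus:
    """Split and dictionary-tag every document that is not already pre-tagged."""
    n_tagged = 0
    for doc in corpus:
        if doc.is_tagged:
            continue
        split_document(doc, include_title=include_title)
        if lexicons:
            tag_document(doc, lexicons)
        n_tagged += 1
    log.info("tagged %d documents (%d arrived pre-tagged)", n_tagged, len(corpus) - n_tagged)
    return corpus


def compute_scores(
    corpus: Corpus,
    coin_cfg: CoinConfig,
    grouping: str = "per_query",
    edge_rule: str = "shared_pair",
):
    """Features, per-group networks, centralities and combined ranked lists.

    Returns ``(features, networks, centrality_maps, ranked_lists)`` where
    ``centrality_maps`` maps "betweenness"/"pagerank" to per-doc scores
    over the whole corpus and ``ranked_lists`` holds one
    :class:`~cointriage.ranking.RankedList` per group.
    """
    features = zscore_normalize(article_features(corpus), grouping=grouping)
    by_doc = {f.doc_id: f for f in features}

    if grouping == "per_query":
        groups = corpus.by_query()
    else:
        groups = {None: list(corpus)}

    networks = {}
    bet_all: dict[str, float] = {}
    pr_all: dict[str, float] = {}
    ranked_lists: list[RankedList] = []
    for qid in sorted(groups, key=lambda q: (q is None, q)):
        members = groups[qid]
        net = build_network(
            {d.doc_id: by_doc[d.doc_id].pairs for d in members}, edge_rule=edge_rule
        )
        networks[qid] = net
        bet = betweenness(net)
        pr = pagerank(net)
        bet_all.update(bet)
        pr_all.update(pr)
        group_feats = [by_doc[d.doc_id] for d in members]
        scores = coin_index(group_feats, {"betweenness": bet, "pagerank": pr}, coin_cfg)
        gold = {d.doc_id: d.gold_label for d in members}
        ranked_lists.append(rank_articles(scores, gold=gold, query_id=qid))
    centrality_maps = {"betweenness": bet_all, "pagerank": pr_all}
    return features, networks, centrality_maps, ranked_lists


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full workflow and write every artifact.

    Returns a summary dict with artifact paths and headline metrics.
    Re-running with identical inputs and config reproduces identical
    ranked output.
    """
    cfg.validate()
    os.makedirs(cfg.out_dir, exist_ok=True)

    try:
        corpus = read_corpus(cfg.corpus_path, format=cfg.corpus_format)
    except Exception as exc:
        raise PipelineError("corpus", cfg.corpus_path, exc) from exc
    log.info("read %d documents, %d queries", len(corpus), len(corpus.queries))

    try:
        lexicons = _load_lexicons(cfg)
        ensure_tagged(corpus, lexicons, include_title=cfg.include_title)
    except Exception as exc:
        raise PipelineError("tagger", "dictionary tagging", exc) from exc
    n_mentions = sum(len(s.mentions) for d in corpus for s in d.sentences)
    log.info("%d entity mentions over %d documents", n_mentions, len(corpus))

    try:
        features, networks, centralities, ranked_lists = compute_scores(
            corpus, cfg.coin, grouping=cfg.grouping, edge_rule=cfg.edge_rule
        )
    except Exception as exc:
        raise PipelineError("scoring", "features/network/ranking", exc) from exc
    n_pairs = sum(f.gcd_count for f in features)
    n_edges = sum(net.n_edges() for net in networks.values())
    log.info("%d concept-pair occurrences, %d network edges", n_pairs, n_edges)

    paths = {name: os.path.join(cfg.out_dir, name) for name in (
        "features.csv", "edges.tsv", "network.graphml", "centrality.csv",
        "ranked.tsv", "feature_matrix.csv", "eval.json", "manifest.json",
    )}
    write_feature_csv(features, paths["features.csv"])

    # per-group networks merged for export; vertex sets are disjoint
    import networkx as nx

    from .network import CooccurrenceNetwork

    merged = CooccurrenceNetwork(graph=nx.compose_all([n.graph for n in networks.values()]))
    write_edgelist_tsv(merged, paths["edges.tsv"])
    write_graphml(merged, paths["network.graphml"])
    write_centrality_csv(centralities["betweenness"], centralities["pagerank"], paths["centrality.csv"])

    entries = []
    for ranked in ranked_lists:
        entries.extend(ranked.entries)
    write_ranked_tsv(entries, paths["ranked.tsv"])
    write_feature_matrix(export_features(features, centralities), paths["feature_matrix.csv"])

    summary: dict = {"n_documents": len(corpus), "n_mentions": n_mentions,
                     "n_pair_occurrences": n_pairs, "n_edges": n_edges,
                     "artifacts": paths}
    labeled = [d for d in corpus if d.gold_label is not None]
    if labeled:
        try:
            result = evaluate(
                [r for r in ranked_lists if any(l is not None for l in r.labels())],
                k_set=cfg.k_set,
            )
        except Exception as exc:
            raise PipelineError("evaluation", "MAP/P@k", exc) from exc
        with open(paths["eval.json"], "w", encoding="utf-8") as fh:
            json.dump(result.to_dict(), fh, indent=2, sort_keys=True)
        summary["MAP"] = result.map
    else:
        paths.pop("eval.json")

    manifest = {
        "package": "cointriage",
        "version": __version__,
        "seed": cfg.seed,
        "config": _config_dict(cfg),
    }
    with open(paths["manifest.json"], "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return summary


def _config_dict(cfg: RunConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["k_set"] = list(cfg.k_set)
    return d
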