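"""Combined co-occurrence + network ranking.

The final article score is a convex combination of the co-occurrence model
and the network model,

    CoIN_index = α · scale(co-occurrence score) + (1 − α) · scale(network score),

where α ∈ [0, 1] weights the concept-pair evidence against the network
centrality.  The two raw scales (a summed z-score or raw pair count vs a
probability mass or path count) are incomparable, so both scores are
standardized per group before combining (``score_scaling="zscore"``,
default); min–max scaling and no scaling are available for sensitivity
checks.  Defaults α = 0.1, co-occurrence score = total pair frequency
(gcd), network score = PageRank.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .cooccur import ArticleFeatures

COOCCUR_SCORES = ("z_total", "gcd_count", "cd", "cg", "gd")
NETWORK_SCORES = ("pagerank", "betweenness")
SCALINGS = ("zscore", "minmax", "none")


@dataclass
class CoinConfig:
    """Configuration of the combined ranking score."""

    alpha: float = 0.1
    cooccur_score: str = "gcd_count"
    network_score: str = "pagerank"
    score_scaling: str = "zscore"

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.cooccur_score not in COOCCUR_SCORES:
            raise ValueError(f"unknown cooccur_score {self.cooccur_score!r}")
        if self.network_score not in NETWORK_SCORES:
            raise ValueError(f"unknown network_score {self.network_score!r}")
        if self.score_scaling not in SCALINGS:
            raise ValueError(f"unknown score_scaling {self.score_scaling!r}")


@dataclass
class RankedList:
    """A ranked list of articles for one query."""

    query_id: Optional[str]
    # (rank starting at 1, doc_id, score, gold label)
    entries: list[tuple[int, str, float, Optional[bool]]] = field(default_factory=list)

    def doc_ids(self) -> list[str]:
        return [e[1] for e in self.entries]

    def labels(self) -> list[Optional[bool]]:
        return [e[3] for e in self.entries]


def _raw_cooccur(f: ArticleFeatures, which: str) -> float:
    return {
        "z_total": f.z_total,
        "gcd_count": float(f.gcd_count),
        "cd": float(f.cd_count),
        "cg": float(f.cg_count),
        "gd": float(f.gd_count),
    }[which]


def _scale(values: np.ndarray, how: str) -> np.ndarray:
    if how == "none" or len(values) < 2:
        return values.astype(float)
    if how == "zscore":
        s = values.std(ddof=1)
        return np.zeros_like(values, dtype=float) if s == 0 else (values - values.mean()) / s
    if how == "minmax":
        span = values.max() - values.min()
        return np.zeros_like(values, dtype=float) if span == 0 else (values - values.min()) / span
    raise ValueError(f"unknown scaling {how!r}")


def coin_index(
    features: Sequence[ArticleFeatures],
    centralities: Mapping[str, Mapping[str, float]],
    cfg: CoinConfig,
) -> dict[str, float]:
    """Combined score per document for one group (e.g. one query).

    ``centralities`` maps "betweenness" and "pagerank" to per-doc score
    dicts covering every document in ``features``.  Scaling is applied
    across the group as configured, then scores are combined as
    α·cooccurrence + (1 − α)·network.
    """
    net = centralities[cfg.network_score]
    missing = [f.doc_id for f in features if f.doc_id not in net]
    if missing:
        raise KeyError(f"no {cfg.network_score} score for documents {missing[:5]}")
    co = np.array([_raw_cooccur(f, cfg.cooccur_score) for f in features])
    nw = np.array([net[f.doc_id] for f in features], dtype=float)
    combined = cfg.alpha * _scale(co, cfg.score_scaling) + (1.0 - cfg.alpha) * _scale(
        nw, cfg.score_scaling
    )
    return {f.doc_id: float(s) for f, s in zip(features, combined)}


def rank_articles(
    scores: Mapping[str, float],
    gold: Optional[Mapping[str, Optional[bool]]] = None,
    query_id: Optional[str] = None,
) -> RankedList:
    """Order documents by descending score; ties break by ascending doc_id."""
    for doc_id, s in scores.items():
        if math.isnan(s):
            raise ValueError(f"NaN score for document {doc_id!r}")
    ordered = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    entries = [
        (rank, doc_id, score, gold.get(doc_id) if gold else None)
        for rank, (doc_id, score) in enumerate(ordered, start=1)
    ]
    return RankedList(query_id=query_id, entries=entries)


FEATURE_MATRIX_HEADER = ("cd", "cg", "gd", "gcd", "betweenness", "pagerank", "label")


def export_features(
    features: Sequence[ArticleFeatures],
    centralities: Mapping[str, Mapping[str, float]],
) -> list[tuple]:
    """Feature-matrix rows for an external classifier.

    One row per document with columns cd, cg, gd, gcd, betweenness,
    pagerank, label (the fixed :data:`FEATURE_MATRIX_HEADER` order); this
    is the input a linear-kernel SVM or similar would train on.  Raises
    ``KeyError`` when a centrality is missing for some document.
    """
    rows = []
    for f in features:
        try:
            bet = centralities["betweenness"][f.doc_id]
            pr = centralities["pagerank"][f.doc_id]
        except KeyError as exc:
            raise KeyError(f"missing centrality for document {f.doc_id!r}") from exc
        rows.append((f.cd_count, f.cg_count, f.gd_count, f.gcd_count, bet, pr, f.gold_label))
    return rows


def write_feature_matrix(rows: Sequence[tuple], path) -> None:
    """Write the feature matrix as CSV with the fixed header."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(",".join(FEATURE_MATRIX_HEADER) + "\n")
        for cd, cg, gd, gcd, bet, pr, label in rows:
            lab = "" if label is None else str(int(label))
            fh.write(f"{cd},{cg},{gd},{gcd},{bet:.10g},{pr:.10g},{lab}\n")
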