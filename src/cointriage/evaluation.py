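"""Ranking metrics and class-difference significance testing.

Relevance is the gold curation label: an article counts as relevant when a
curator recorded at least one interaction for it.  Metrics:

* P@k — precision among the top k ranked articles (# relevant / k; k is
  the denominator even when the list is shorter);
* AP — average precision of one ranked list: the mean, over the query's
  relevant articles, of the precision at each relevant rank (standard IR
  denominator: total relevant in the gold set);
* MAP — the arithmetic mean of per-query APs.

``feature_ttest`` compares a feature (e.g. the total pair count gcd)
between curated and non-curated articles with a two-sided independent
two-sample t-test, Welch's variant by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

from scipy import stats

from .ranking import RankedList

log = logging.getLogger(__name__)

DEFAULT_K_SET = (10, 20, 50, 100)


@dataclass
class EvalResult:
    """MAP, per-query AP and the P@k grid for one evaluation run."""

    map: float
    per_query_ap: dict[str, float]
    p_at_k: dict[str, dict[int, float]]
    n_relevant: dict[str, int]
    skipped_queries: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "MAP": self.map,
            "per_query_AP": self.per_query_ap,
            "P_at_k": {q: {str(k): v for k, v in grid.items()} for q, grid in self.p_at_k.items()},
            "n_relevant": self.n_relevant,
            "skipped_queries": self.skipped_queries,
        }


def _relevance(ranked: RankedList) -> list[bool]:
    rel = []
    for _, doc_id, _, label in ranked.entries:
        if label is None:
            raise ValueError(f"document {doc_id!r} has no gold label")
        rel.append(bool(label))
    return rel


def precision_at_k(ranked: RankedList, k: int) -> float:
    """Fraction of the top k ranked documents that are relevant."""
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    rel = _relevance(ranked)
    return sum(rel[:k]) / k


def average_precision(ranked: RankedList) -> float:
    """Average precision of one ranked list.

    Sums P@i over the ranks i holding relevant documents and divides by
    the total number of relevant documents.  Raises ``ValueError`` when
    the list contains no relevant document (AP is undefined).
    """
    rel = _relevance(ranked)
    n_relevant = sum(rel)
    if n_relevant == 0:
        raise ValueError(
            f"query {ranked.query_id!r} has no relevant documents; AP undefined"
        )
    hits = 0
    total = 0.0
    for i, r in enumerate(rel, start=1):
        if r:
            hits += 1
            total += hits / i
    return total / n_relevant


def mean_average_precision(per_query: Sequence[float]) -> float:
    """Arithmetic mean of per-query average precisions."""
    if not per_query:
        raise ValueError("MAP of an empty query set is undefined")
    return sum(per_query) / len(per_query)


def evaluate(
    ranked_lists: Sequence[RankedList], k_set: Sequence[int] = DEFAULT_K_SET
) -> EvalResult:
    """MAP, per-query AP and P@k over a set of per-query ranked lists.

    Queries without any relevant document are excluded from MAP with a
    logged warning and listed in ``skipped_queries``.
    """
    per_query_ap: dict[str, float] = {}
    p_at_k: dict[str, dict[int, float]] = {}
    n_relevant: dict[str, int] = {}
    skipped: list[str] = []
    for ranked in ranked_lists:
        qid = str(ranked.query_id)
        rel = _relevance(ranked)
        n_relevant[qid] = sum(rel)
        p_at_k[qid] = {k: precision_at_k(ranked, k) for k in k_set}
        if n_relevant[qid] == 0:
            log.warning("query %s has no relevant documents; excluded from MAP", qid)
            skipped.append(qid)
            continue
        per_query_ap[qid] = average_precision(ranked)
    if not per_query_ap:
        raise ValueError("no query with defined AP")
    return EvalResult(
        map=mean_average_precision(list(per_query_ap.values())),
        per_query_ap=per_query_ap,
        p_at_k=p_at_k,
        n_relevant=n_relevant,
        skipped_queries=skipped,
    )


def feature_ttest(
    curated_values: Sequence[float],
    noncurated_values: Sequence[float],
    equal_var: bool = False,
) -> float:
    """Two-sided independent two-sample t-test p-value.

    Welch's unequal-variance variant by default; pass ``equal_var=True``
    for the pooled-variance test.  Each group needs at least two values.
    """
    if len(curated_values) < 2 or len(noncurated_values) < 2:
        raise ValueError("each group needs at least 2 values for a t-test")
    res = stats.ttest_ind(curated_values, noncurated_values, equal_var=equal_var)
    return float(res.pvalue)


def feature_report(
    features, value_names: Sequence[str] = ("cd_count", "cg_count", "gd_count", "gcd_count"),
    extra: Optional[dict] = None,
    equal_var: bool = False,
) -> dict[str, float]:
    """Per-feature t-test p-values between curated and non-curated articles.

    ``features`` is a list of :class:`~cointriage.cooccur.ArticleFeatures`
    with gold labels; ``extra`` may add named per-doc score dicts (e.g.
    centralities) to the comparison.  Returns feature name → p-value.
    """
    curated = [f for f in features if f.gold_label]
    noncur = [f for f in features if f.gold_label is False]
    report: dict[str, float] = {}
    for name in value_names:
        report[name] = feature_ttest(
            [float(getattr(f, name)) for f in curated],
            [float(getattr(f, name)) for f in noncur],
            equal_var=equal_var,
        )
    if extra:
        for name, scores in extra.items():
            report[name] = feature_ttest(
                [scores[f.doc_id] for f in curated],
                [scores[f.doc_id] for f in noncur],
                equal_var=equal_var,
            )
    return report
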