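# cointriage

Ranking biomedical articles for curation priority by combining
sentence-level concept-pair statistics with centralities of an
article-level co-occurrence network.

Biological databases such as the Comparative Toxicogenomics Database are
filled by curators who read papers and record chemical–gene–disease
interactions. Triage — deciding which articles are worth a curator's time —
is a ranking problem: given a list of articles retrieved for a target
chemical, order them so curatable articles come first. `cointriage`
implements a network-based scorer for this task, evaluated with mean
average precision (MAP) and P@k.

## The method

1. **Concept pairs.** Each article is split into sentences and tagged for
   gene, chemical and disease names (a dictionary tagger is built in;
   pre-tagged corpora from external NER tools are accepted as-is). A
   *concept pair* is two entities of different classes in one sentence,
   typed cd (chemical–disease), cg (chemical–gene) or gd (gene–disease);
   `gcd` is their total. Per article, each pair-type count *x* is
   standardized within its query group, *z* = (*x* − μ)/*S*, and the
   **normalized co-occurrence score** is *z*<sub>cd</sub> + *z*<sub>cg</sub> + *z*<sub>gd</sub>.
2. **Co-occurrence network.** Articles are vertices; an undirected edge
   joins two articles that share an identical concept pair. Two
   centralities score each article:
   *betweenness* C<sub>B</sub>(v) = Σ<sub>s≠v≠t</sub> σ<sub>st</sub>(v)/σ<sub>st</sub>
   (raw shortest-path units, no normalization), and *PageRank*
   PR(V<sub>i</sub>) = (1 − d)/N + d · Σ<sub>j∈In(V<sub>i</sub>)</sub> PR(V<sub>j</sub>)/|Out(V<sub>j</sub>)|
   with damping d = 0.85 and each undirected edge counted as a
   bidirectional link.
3. **Combined score.** The final ranking score is the convex combination
   CoIN_index = α · scale(co-occurrence score) + (1 − α) · scale(network score),
   default α = 0.1 with the gcd frequency and PageRank.

On the classic five-article worked example (edges P1–P2, P2–P3, P2–P4,
P3–P4, P4–P5), the two bridging articles dominate both centralities:
PR(P2) = PR(P4) = 0.29, PR(P3) = 0.19, PR(P1) = PR(P5) = 0.11, and
betweenness 3/3/0/0/0.

## Worked example

Generate a seeded synthetic triage benchmark (3 queries × 200 articles,
30% curatable, curatable articles mention concept pairs at 3× the
background rate and reuse a shared pair pool) and run the full pipeline:

```sh
coin synth --seed 1 --out corpus.jsonl
coin run --corpus corpus.jsonl --alpha 0.1 --cooccur gcd --network pagerank \
    --out-dir out/
```

which prints

```json
{
  "n_documents": 600,
  "n_mentions": 4156,
  "n_pair_occurrences": 3200,
  "n_edges": 2756,
  "MAP": 0.9872502418184288
}
```

600 articles carried 4156 tagged mentions and 3200 sentence-level pair
occurrences; shared pairs induced 2756 edges across the three per-query
networks; ranking by the combined score put curatable articles near the
top of every list (MAP 0.987 against the generator's gold labels; a random
ordering of the same lists scores ≈ 0.3). `out/` contains the feature
table, the network (edge list + GraphML), centralities, the ranked list
and the evaluation JSON, plus a manifest with the resolved configuration.

Each stage is also exposed separately (`coin tag`, `coin pairs`,
`coin network`, `coin rank`, `coin eval`) and communicates through plain
text formats, so external NER output or an external classifier can be
substituted at any point. `coin run --help` lists all options.

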