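# Methods

## Model and procedure

`cointriage` scores articles for curation priority in four stages.

**Sentence splitting and tagging.** Title and abstract are concatenated
(a terminal "." is appended to the title if missing; `include_title=False`
removes the title from pair extraction) and split after `.`, `!` or `?`
followed by whitespace. Abbreviation handling is deliberately not
attempted: the rule is deterministic and adequate for abstracts, but will
over-split text containing "e.g. " or "Dr. Smith". Entity tagging is
dictionary-based: case-insensitive, longest-match-first, left-to-right,
on token boundaries (maximal alphanumeric runs; hyphens and punctuation
separate tokens, so a term can never match inside a longer word).
Multi-word terms are matched after whitespace/hyphen normalization. When
dictionaries of two classes contain the same term, the fixed precedence
chemical > gene > disease applies and a warning is logged; real NER
ambiguity is better resolved upstream, and pre-tagged input (JSONL with
per-sentence mention spans) bypasses both splitting and tagging.

**Concept pairs.** Within a sentence, every unordered pair of *distinct
normalized names* from two different classes counts once; per-document
counts sum over sentences. Counting name types rather than mention tokens
bounds the inflation that repeated mentions of one name would cause.
Per-document counts x (one per pair type cd/cg/gd) are standardized to
z = (x − μ)/S with the *sample* standard deviation (n − 1). The
standardization population is the per-query article list by default
(`grouping="global"` uses the whole corpus); ranked lists are evaluated
per query, so per-query normalization keeps scores comparable where they
compete. S = 0 or a singleton group yields z = 0, keeping scores finite.
The normalized co-occurrence score is z_cd + z_cg + z_gd.

**Network.** Vertices are articles of one query group (a global network
is available). The default edge criterion is *shared identical pair*: an
edge joins two articles containing the same canonical concept pair. The
weaker reading — any pair of the same type in both articles — is
implemented as `edge_rule="same_type"`; it produces near-complete graphs
on realistic corpora and is off by default. Edges record the shared pairs
and their types, but centralities use the simple unweighted graph; no
principled weighting presented itself, and a shared-pair-count weight is
deliberately not the default.

- *Betweenness*: Σ over unordered vertex pairs {s, t} (endpoints
  excluded) of σ_st(v)/σ_st, fractional credit for tied shortest paths,
  unreachable pairs contribute 0, **no normalization** (the worked
  five-vertex example's value of 3 is in these raw units). Computed via
  networkx's Brandes implementation; the test suite checks it against an
  independent brute-force BFS path-enumeration oracle.
- *PageRank*: power iteration of
  PR(V_i) = (1 − d)/N + d·Σ_{j∈In(V_i)} PR(V_j)/|Out(V_j)|, every
  undirected edge counted as one in-link and one out-link at each
  endpoint. The (1 − d)/N teleport form is the variant that conserves
  Σ PR = 1 and is the only one consistent with the worked example's
  printed values (0.29/0.19/0.11). Defaults: d = 0.85, tol = 1e-10 on the
  max absolute per-vertex change, max_iter = 1000; non-convergence raises
  with the final residual. Isolated vertices have no out-links; their
  damped mass is redistributed uniformly (the standard dangling-node
  treatment), which preserves conservation on disconnected networks.

**Combined ranking.** CoIN_index = α·scale(co-occurrence) +
(1 − α)·scale(network), α ∈ [0, 1]. The co-occurrence score is one of
{z_total, gcd, cd, cg, gd}; the network score is PageRank or betweenness.
Because the two raw scales are incomparable (a summed z-score vs a
probability mass), both are z-standardized per group before combining
(`score_scaling`: zscore | minmax | none), which makes α interpretable as
a genuine mixing weight. Defaults α = 0.1, gcd + PageRank — the
combination that performed best on the original benchmark. At α = 1 or
α = 0 the ranking is exactly the single-model ranking: z-scaling is
strictly increasing whenever the raw scores differ, and the degenerate
all-equal case ties either way. Ties always break by ascending doc_id.

**Evaluation.** P@k = (#relevant in top k)/k, with k the denominator even
past the list end. AP averages P@i over relevant ranks i, divided by the
query's total relevant count (standard IR denominator). MAP is the
arithmetic mean of per-query APs; queries with zero relevant documents
are excluded with a logged warning. The class-difference report uses a
two-sided independent two-sample t-test, Welch's variant by default
(`equal_var=True` gives the pooled test for comparability with analyses
that used it).

## Synthetic benchmark generator

The generator emulates the structure of a chemical-triage benchmark:
`n_queries` per-chemical article lists, a curatable minority
(`frac_curatable`) whose sentences draw Poisson-distributed co-mention
events at `pair_rate_curatable` per sentence versus
`pair_rate_noncuratable` for the rest, and a per-query "hot pool" of
`shared_pair_pool` concept pairs that curatable articles reuse with
probability `pool_affinity` — which is what gives curatable articles
shared-pair edges and higher centrality. Defaults (3 queries × 200
documents, 30% curatable, 4–8 sentences per document, rates 0.9 vs 0.3 —
a 3× enrichment in the direction observed on real curated corpora —
pool 20, affinity 0.8, vocabularies of 150 genes / 100 chemicals /
120 diseases) describe a mid-sized benchmark in which both the
co-occurrence and the network signal are present but noisy. Entity names
are fixed synthetic vocabulary tokens (`GENE0001`, `CHEM0001`,
`DIS0001`, …) inserted into templated sentences; the first sentence
doubles as the title, so re-splitting and re-tagging the plain text
reproduces the emitted pre-tagged records exactly. One seeded numpy
generator drives everything; identical configs are byte-identical.

What the generator does **not** emulate: linguistic variety, NER errors
(names are always recovered exactly), synonymy between chemical names,
abbreviations, section structure, and the real curation criteria that
make some target chemicals much harder than others. Passing tests on
synthetic corpora therefore demonstrate that the pipeline recovers the
statistical structure it assumes — enriched pair counts and shared-pair
connectivity among curatable articles — not that it reaches any
particular performance on real curation corpora, where tagging noise and
weaker class separation dominate.

## Numerical choices and degenerate inputs

- Sample SD (ddof = 1) throughout; zero variance or singleton groups give
  z = 0 rather than NaN.
- PageRank starts from the uniform vector; convergence is max-norm.
- A corpus with no mentions at all yields all-zero scores; ranking then
  falls back to the doc_id tie-break and evaluation still runs.
- NaN scores are rejected by name at ranking time rather than silently
  sorting.
- Problem sizes in the test suite (corpora of tens to hundreds of
  documents, 5–10 replicate seeds, 100–300 significance replicates,
  200 random graphs of ≤ 8 vertices for the centrality oracle) were
  chosen to exercise the asymptotic claims at desk scale while keeping
  the whole suite near ten seconds.

## Known limitations

- The sentence splitter's abbreviation blindness (above).
- Dictionary tagging cannot resolve genuinely ambiguous names; the fixed
  class precedence is a reproducibility device, not a disambiguator.
- The shared-identical-pair edge rule is strict: articles discussing the
  same chemical–disease theme with different entity spellings are not
  linked unless normalization unifies them.
- α is a fixed configuration constant; no selection procedure is
  provided, and no classifier is trained — `export_features` produces
  the (cd, cg, gd, gcd, betweenness, pagerank, label) matrix for any
  external learner.
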