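# Methods

## The probabilistic model

The build treats a corpus of `N` proteins as the sampling universe.
For a term `t` annotating `K` proteins and a domain `d` carried by `n`
proteins, the overlap count `k` is, under independence, hypergeometric:
`P(X = i) = C(K, i) C(N−K, n−i) / C(N, n)`. Three statistics are
derived per (term, domain) cell:

* **p-value** — the exact one-sided tail `P(X ≥ k)`, computed with
  `scipy.stats.hypergeom.sf(k−1, N, K, n)`. No normal approximation is
  used anywhere; the test suite checks exact agreement with a
  brute-force tail enumeration for every parameter combination with
  `N ≤ 25`.
* **FDR** — Benjamini–Hochberg step-up adjustment
  (`statsmodels.stats.multitest`), applied jointly across all tested
  cells of one build (one ontology × one domain type). Cells with
  `k = 0` have one-sided p exactly 1 and are excluded from the family;
  the minimum tested overlap is configurable (`min_k`, default 1), as
  are optional marginal filters (`min_K`, `min_n`, default off).
* **annotation score** — the z-form strength `s = (k − μ)/σ` with
  `μ = nK/N` and `σ² = n (K/N)(1 − K/N)(N − n)/(N − 1)`, rescaled
  linearly so the weakest significant pair scores 1 and the strongest
  100. The z-form was chosen because it is a strength measure distinct
  from the p-value, well defined for rescaling, and reusable unchanged
  as the enrichment z-score; if all significant strengths coincide the
  score is 100, and `σ = 0` (including `N < 2`) yields `s = 0`. The
  rescaling is performed over the significant *direct* records of one
  build, before propagation.

## Counting conventions

* **Universe** — proteins present in both inputs (term-annotated and
  domain-assigned). Fisher's 2×2 table needs a common background;
  proteins seen in only one input carry no information about the
  association. A synthetic corpus of 500 proteins therefore typically
  contributes a build universe somewhat below 500 (unannotated
  proteins drop out).
* **Closure before counting** — each protein's term set is closed
  under ancestors before the matrix is built. Without this,
  `K(parent) < K(child)` anomalies arise and the hypergeometric model
  is inconsistent across levels; with it the True Path Rule holds for
  the marginals themselves (property-tested).
* **Domain multiplicity** — a protein contributes at most 1 to `n(d)`
  and `k(t, d)` however many copies of `d` it carries; the matrix
  counts proteins.
* **Relations** — only `is_a` edges propagate by default. `part_of`
  can be enabled (`include_part_of`), but is off because `is_a` is the
  one relation for which the True Path Rule is universally sound.
  Obsolete terms are dropped at parse time; `alt_id` aliases resolve to
  their primary identifier so corpus annotations using superseded
  accessions are not lost. Multiple roots (e.g. the three GO
  namespaces) are kept as separate sub-DAGs; no artificial super-root
  is introduced.
* **Evidence codes** — the GAF reader keeps all evidence codes by
  default and exposes an exclusion set (e.g. `{"IEA"}`); rows with a
  `NOT` qualifier are always dropped.

## Propagation

For each domain, every strict ancestor of an annotated term receives a
record. A propagated record carries the maximum score (and strength)
and the minimum p/FDR over the domain's annotated descendants of that
ancestor; a term that already holds a direct record keeps it, raising
its score to the propagated value where that is larger. Maximum was
chosen as the aggregation because it preserves monotonicity toward the
root and never understates the support below a term; sums would
double-count nested descendants. The resulting table is closed under
ancestors and score-monotone along every `is_a` path, and both
invariants are re-checked on randomized DAG/table instances in the
test suite.

## Enrichment analysis

Given a user domain list and a reference annotation table, the universe
is the set of reference-annotated domains (the standard enrichment
convention; a user background list can replace it, in which case input
domains outside the background are an error rather than silently
dropped — that situation almost always means a mismatched domain
type). Input identifiers absent from the reference are reported as
dropped, never silently discarded. For each term with `K` annotated
domains and overlap `k` against the `n` usable input domains, the same
exact test and z-form are computed, BH-adjusted across the tested
terms. By default only terms overlapping at least one usable input
domain are tested (a deterministic, documented family size `m`);
`test_all_terms` switches to testing every reference term. Results are
sorted by FDR ascending, ties by z descending, then term id; an FDR
threshold of exactly 1 disables the significance filter so overlap
counts can be inspected. Reports are TSV plus a dot-plot data file
(term, z, FDR) for the leading `top_n` terms.

## Synthetic corpora

The generator emulates the minimal structure the inference needs: an
ontology (a complete rooted tree of configurable depth and branching,
terms numbered breadth-first), a domain catalogue with per-domain
prevalence, and planted (domain, term) associations. Defaults: 500
proteins; six domains at prevalence 0.3; a depth-3 binary tree (15
terms, 8 leaves); three planted pairs at within-domain term rate 0.9
versus background rate 0.05; unplanted leaves attached at base rate
0.05. Planted terms are always leaves, so ancestors acquire their
annotations only through propagation and propagation itself is
assertable. All draws flow from one seeded `numpy` generator — no
global random state — and fixtures are emitted in exactly the GAF and
TSV dialects the readers consume, so round-trip tests exercise the
real parsers.

What the generator does **not** model: domain co-occurrence
correlation (domains are drawn independently), realistic domain
architectures or sequence content, annotation depth heterogeneity, and
evidence-code structure. Passing recovery benchmarks therefore show
that the statistics behave correctly under the stated sampling model,
not that real-corpus biases (study bias, IEA error structure,
correlated architectures) are handled.

## Numerical and tie-breaking choices

* Default build FDR threshold 10⁻³ (conservative, annotation-resource
  setting); default enrichment FDR 0.05, `min_overlap` 1, `top_n` 5.
* All tabular outputs are sorted deterministically (annotation tables
  by domain then term; enrichment by FDR/z/term id; members
  lexicographically) and floats are serialized with full `repr`
  precision, so re-runs with one seed are byte-identical and report
  round-trips are exact.
* Writes are atomic (temp file + rename): a failing run leaves no
  partial output.
* Degenerate inputs: an empty tested set yields an empty table with a
  warning; a single-value rescale maps to 100; proteins drawing an
  empty domain set in the generator are redrawn (bounded retries).

## Problem sizes used in the checks

The shipped benchmarks use corpora of 500 proteins over 20 seeds for
recovery (and 300 proteins for the determinism re-run), exhaustive
Fisher-oracle comparison up to `N = 25` (≈ 24k tables), 200 randomized
propagation instances, and 1,000 random vectors for BH permutation
invariance. These sizes give stable pass/fail behaviour at
desk-machine cost; the statistics themselves are size-agnostic.

## Known limitations

* The annotation-score formula reproduces the published *form* of the
  dcGO score (a hypergeometric-distribution-based strength rescaled to
  1–100); the production database's exact anchor points are not public,
  so scores here are comparable within a build, not against the hosted
  resource.
* Z-scores and FDRs of the hosted enrichment service depend on the full
  reference corpus and are not reproducible from the shipped miniature
  example; only overlap counts and member lists are.
* OWL ontologies, cross-ontology bridging axioms and reasoning beyond
  transitive closure are out of scope, as are UniProt identifier
  mapping and any network fetching.
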