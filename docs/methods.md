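# Methods

## Model

The toolkit treats a drug–gene relation as a translation in embedding
space. With concept embeddings `u_w ∈ R^K` and a relation set
`R ⊂ D_all × G_all`, the working assumption is

    u_d + v ≈ u_g        for (d, g) ∈ R,

and `v` is estimated by the pair-mean estimator
`v̂ = E_R{u_g − u_d}`, which is algebraically identical to the difference
of pair-projected means `E_R{u_g} − E_R{u_d}` (each pair contributes its
drug and its gene once). The naive alternative `E_G{u_g} − E_D{u_d}`
averages over *all* drugs and genes, related or not; the two coincide
exactly when R is complete bipartite. Restricted variants — per pathway
(`v̂_p` from `R_p`), per year slice (`v̂^y` from `R^y`), or from the
"known" part of a year slice — are the same estimator applied to the
restricted pair set, not separate code paths.

Uncertainty: for the pair-mean estimator the per-dimension standard
error is `sd(u_g − u_d)/√|R|`, reported by the Results object. It is a
descriptive diagnostic (pairs sharing a drug or gene are not
independent), not a basis for formal inference.

## Scoring and ranking

A candidate gene g is scored for query drug d by

    cos(u_d − c + v̂,  u_g − c),

where `c` is the mean embedding of the candidate search space (the full
gene universe of the evaluated relation data, or its year slice).
Centering both operands by the same `c` removes the dependence of cosine
similarity on the embedding origin; it also makes the ranking invariant
under any global translation of the embeddings, and the cosine itself is
invariant under global orthogonal maps and positive rescaling (all three
covered by tests). The query is centered by the *gene* mean even though
it is a drug — this is deliberate and matches the centered scoring
formula; whether the pairs feeding `v̂` are centered first is immaterial,
since any constant cancels in the differences.

Ties are broken by ascending candidate identifier via a stable sort, so
rankings are reproducible across platforms. Scoring is exact and
exhaustive (double precision, no approximate nearest-neighbour index);
search spaces up to ~10^5 candidates are handled as a single
matrix-vector product per query. A candidate whose centered vector has
zero norm receives score −inf and is counted, never silently dropped.
The reverse task (predict drugs from a gene) mirrors the forward task:
−v̂ is added to the gene query and centering is over the drug universe.

## Evaluation settings

* **G** — estimator from R; queries the related drugs D; answers `[d]`;
  search space the full gene universe.
* **P1** — per eligible pathway p: estimator from `R_p`; queries the
  drugs related within p; answers `[d]_p`. The search space remains the
  full gene universe, not the pathway members.
* **P2** — identical predictions to P1, but any globally related gene
  counts as correct, and the query set is every pathway-member drug with
  at least one global relation.
* **Y1** — setting G on the year slice `R^y` (pairs whose drug and gene
  both first appeared by year y; universes shrink accordingly). At the
  maximal year it reproduces setting G exactly (asserted in tests).
* **Y2** — estimator from the known pairs (co-appearance year ≤ y);
  answers only the unknown pairs (co-appearance after y); queries
  restricted to drugs with a non-empty reduced answer set.
* **P1Y1 / P2Y1 / P1Y2 / P2Y2** — pathway restriction applied first,
  then the year logic within each pathway (P2-type settings score
  against the global year-sliced answer sets).

Pathway eligibility requires ≥ 2 distinct related drugs *and* ≥ 2
distinct related genes inside `R_p`; one-drug or one-gene pathways make
the restricted task degenerate and are excluded. A pair whose
co-appearance year is absent is treated as never co-appeared — always
unknown — which keeps the known/unknown split a true partition of `R^y`.

Metrics: top-k accuracy (a query is a hit if *any* of the k
highest-ranked candidates is in its answer set — the same rule in every
setting, so top-10 can never fall below top-1) and MRR (reciprocal of
the first correct rank, 0 when no correct candidate exists). Aggregates
are micro-averages over query instances; in pathway settings a drug
queried in several pathways contributes once per pathway, and per-query
rows carry the pathway id so other aggregations can be recomputed.
Queries with an empty (possibly reduced) answer set or without an
embedding are excluded and tallied under `skipped`.

Because the toolkit does not train embeddings, year settings on
synthetic or user data reuse one embedding store across cutoffs; only
the vocabulary and relations are year-restricted. With embeddings
retrained per cutoff the same code applies — pass the year-specific
store.

## Random baseline

Genes with at least one relation are ranked by weighted sampling without
replacement, weight `|[g]|`, implemented with exponential sort keys
(Efraimidis–Spirakis), which reproduces the distribution of successive
renormalized draws exactly. One ranking per repeat is shared across all
queries (a per-query variant is available by flag); metrics are averaged
over 10 repeats by default, repeat r seeded with `seed + r`. The
first-draw hit probability has the closed form
`Σ_{g∈[d]} |[g]| / |R|`, used to calibrate the Monte-Carlo estimate.

## Synthetic benchmark

`generate_benchmark` plants the assumed geometry: drug embeddings are
standard normal; each related gene picks 1–3 drugs (configurable
degree distribution) within its pathway and is placed at the *mean* of
its related drugs plus the pathway's planted vector `v*_p` plus
isotropic noise σ. Centering multi-drug genes on their drug mean keeps
the pair-mean estimator exactly unbiased: the within-gene deviations
`mean(u_drugs) − u_d` sum to zero over each gene's pairs, so at σ = 0
the estimator recovers `v*` to machine precision regardless of degree.
Exact top-1 recovery additionally requires one drug per gene (then
`u_g = u_d + v*` exactly and the target is the unique optimum); with
higher degrees the noise-free optimum can be another drug's gene, which
is the expected behaviour of the model, not a defect.

Defaults: 200 drugs, 400 genes (75 % related), K = 50, `‖v*‖ = 3`
(drug vectors have typical norm √50 ≈ 7.1, so the planted signal is
strong but not dominant), σ = 0.05, 4 pathways with distinct shifts,
years uniform on 1975–2023 with pair co-appearance lag ≤ 10 years —
sizes chosen so every setting has a non-trivial search space and the
whole suite runs in seconds. Distinct per-pathway shifts make the
global estimator deliberately misspecified (it averages different
`v*_p`), which is what the pathway-advantage checks measure; recovery
checks that target the global estimator use a shared shift, the regime
where the global model is well-specified. Pair years are
`max(y_d, y_g) + lag`, enforcing the co-appearance inequality by
construction. All randomness flows from one seeded generator, so a
config and seed determine the output byte-for-byte.

What the generator does **not** emulate: corpus statistics of real
literature (embedding anisotropy, frequency effects, polysemous
concepts), overlapping pathway membership, or vocabulary mismatch
between embeddings and relation sources. Passing tests demonstrate the
correctness of the estimators, rankings and evaluation logic under the
model's own assumptions — not the empirical performance of any real
embedding release.

## Packaged data

The ErbB signaling pathway fixture (19 drugs, 84 genes, 34 interaction
pairs, readable names) is shipped as plain TSVs and used for fixture-
integrity checks and as a realistic small pathway instance.

## Design choices

* Identifiers are opaque byte strings; no case folding — concept IDs
  are exact keys.
* Embedding files: word2vec text format is canonical (gzip accepted);
  a headerless TSV dialect is supported for human-readable fixtures.
  Values are held as float64 regardless of file precision.
* Pairs whose drug or gene lacks an embedding are dropped with a count
  before estimation (or raise, configurable); vocabulary mismatch is
  routine with real embedding files.
* The pathway-restricted *naive* estimator (over memberships `D_p`,
  `G_p`) is available by analogy with the global naive estimator but is
  secondary; the pair-mean estimator is the estimator of record.
* The statsmodels-style facade (`DrugGeneAnalogy.fit()` →
  `DrugGeneAnalogyResults`) wraps the functional modules; all
  functionality is equally reachable through the module functions.

## Limitations

* No embedding training: the toolkit consumes embeddings, it does not
  produce them.
* MRR and top-k treat answer sets as flat; no graded relevance.
* The standard errors on `v̂` ignore dependence between pairs sharing a
  concept.
* Year annotations are first-appearance proxies; the known/unknown
  split is only as good as the co-appearance years supplied.
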