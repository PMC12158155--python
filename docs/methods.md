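# Methods

This note records the models, conventions and open design choices behind
`orthomapper`, at the level of detail a maintainer or reviewer needs to
judge what the package's guarantees do and do not cover.

## Ortholog tables and cardinality

A table is a deduplicated set of (source gene, human gene) pairs plus
explicit unmapped records for sources without a homolog. Cardinality is
always recomputed from the table's own bipartite degrees — out-degree
o = |targets(s)|, in-degree i = |sources(t)|; one2one iff o = i = 1,
many2many iff o > 1 and i > 1, one2many otherwise (this bucket therefore
also covers the o = 1, i > 1 "many-to-one" orientation). Type strings in
the file are ignored for classification because any subsetted or filtered
export invalidates them; they are retained only as provenance. The
classification is idempotent and is re-run after every filter, since
removing one branch of a fan-out legitimately turns its sibling one2one.

Identifier matching is case-sensitive by default. The opt-in
case-insensitive mode uppercases both sides, which can merge distinct
sources (their target sets are unioned); this is the documented cost of
bridging mouse Title-case and human UPPER-case symbol conventions, and the
reason it is not the default. Symbols and Ensembl IDs are both accepted
but never translated into each other: a matrix must use the same
identifier space as its table.

## Conversion semantics

The converted matrix is defined entry-wise:
`Y[h, j] = Σ X[s, j]` over sources s retained for target h by the policy.
The three policy axes (`many_to_one` ∈ {sum, max_total, drop_group},
`one_to_many` ∈ {expand, drop}, `unmapped` ∈ {drop, retain_tagged}) are
all exposed rather than hard-coding one behavior, because collision
resolution is genuinely underdetermined: no single choice is right for
both count-level analyses (where `sum` matches pseudo-gene aggregation
semantics) and marker-level analyses (where `max_total` keeps rows
interpretable). The default (sum, expand, drop) loses no mapped signal;
its known side effect — pseudobulk efficiency above 100% when fan-outs
are expanded — is asserted to occur *only* under `expand` and is flagged
in the report rather than hidden.

Decisions a reader might otherwise have to reverse-engineer:

- A source's fan-out is taken from the table, not from the targets that
  happen to survive in a particular matrix; group membership for
  collision handling, by contrast, is evaluated among sources present in
  the matrix (a "group" of one behaves like a plain mapping).
- `max_total` ranks by total count across observations with ties broken
  by lexicographically smallest source id — deterministic by design.
- Output features are sorted lexicographically so results are independent
  of table row order. Retained unmapped rows keep their counts under an
  `unmapped:` prefix and participate in the same ordering.
- The aggregation is a sparse incidence-matrix product with the incidence
  dtype matched to the counts dtype; for integer inputs this is
  bit-identical to the dense definition (verified against an independent
  dense reference in the tests and the acceptance script).
- Real-valued (normalized) matrices are converted with the same rules;
  the report marks the input as non-integer so "count efficiency" is
  interpreted accordingly.
- `conversion_plan` previews per-feature fates without touching counts.
  Because the `max_total` winner depends on row totals, the plan accepts
  the count matrix as an optional argument; `convert_matrix` always
  passes it, so realized fates and plan fates are identical by
  construction. Without counts, all members of a `max_total` group are
  reported as kept — the most a counts-free preview can claim.

## PDX harmonization

Species assignment tries strategies in decreasing order of reliability:
configured genome prefixes (literal match; `_` and `-` both accepted as
the trailing separator, since multi-genome reference pipelines vary),
then table membership, then a symbol-case heuristic (all-uppercase
letters → human, Title-case → non-human). The heuristic exists only
because unprefixed mixed matrices occur in the wild; every report records
which strategy dominated, and a matrix whose features are all ambiguous
is an error rather than a guess.

Ambiguous features default to "treat as human, warn": in a xenograft the
human graft is the analyte, so the asymmetric risk is silently routing a
human gene through the mouse conversion. The harmonized matrix keeps the
human block's original feature order and appends converted-only targets
sorted; this makes a human-only matrix an exact fixed point of
`convert_pdx` and keeps non-colliding human rows bit-identical. The
harmonized counts are returned as a distinct named result ("humanized")
and, on the command line, written beside an untouched copy of the
original — never in place of it.

## QC metrics

Pseudobulk efficiency is `100·total(Y)/total(X)`; per-observation
efficiency is the same ratio per column. Observations with zero source
counts get an *undefined* (NaN) entry plus a warning — never 0 or 100,
which would bias summaries. The exact identity
`pseudobulk = Σ_j eff_j · depth_j / total(X)` (defined entries) is kept as
a test invariant. Gene mapping rate counts features with ≥ 1 target;
biotype retention tallies kept features per gene class, pooling features
without an annotation as "unknown" (with no annotations at all, the single
"unknown" row equals the mapping rate by construction).

Rand index and adjusted Rand index are both always reported, since "the
Rand index" is ambiguous between the raw and chance-adjusted forms and
computing both is free. They are computed from the label contingency via
scikit-learn; the test suite checks them against exhaustive pair
enumeration (exact for all n ≤ 12 fixtures) and a 200-replicate null
calibration (mean ARI of independent uniform labelings within ±0.02 of 0).

## SNN clustering pipeline

`cluster_observations` reproduces the standard single-cell workflow with
every step pinned down for determinism: depth-normalize each observation
to 10,000 counts; log1p; select the top genes by dispersion (variance/mean
of the depth-normalized, pre-log values; ties broken by row order, stable
sort); z-score per gene with values clipped at ±10; PCA via full SVD (no
randomized solver, so no run-to-run drift); k-nearest neighbors by brute
force in component space with self included in each neighbor set;
SNN edges between neighbor pairs weighted by Jaccard similarity of the
two neighbor sets; community detection by seeded modularity optimization
(RB-configuration partition) at the given resolution.

Defaults — `n_top_genes=2000, n_components=20, k_neighbors=20,
resolution=0.8, seed=0` — mirror common single-cell practice; all are
exposed. `n_components` is clamped to min(n−1, selected genes). Two runs
with the same matrix, parameters and seed are label-identical, and a
bijective renaming of features cannot change any numeric step, which is
what makes "concordance = 1 under 1:1 conversion" a meaningful baseline.
The dispersion definition and the un-pruned SNN graph are deliberate
simplifications relative to any particular ecosystem's defaults; the
concordance metrics only ever compare two runs of *this* pipeline, so the
comparison is internally consistent.

## Synthetic generators

`simulate_counts` draws `counts[g, c] ~ NB(μ = base_g · fc_{g,group(c)} ·
size_c, θ)` with log-normal baselines (σ = 1), fold changes
`2^N(0, lfc_scale)` on a `de_fraction` subset, uniform per-cell size
factors, and the variance convention `μ + μ²/θ` (stated because "NB
dispersion" means different things in different ecosystems; larger θ is
*less* dispersed). Defaults — 500 genes, 300 cells, 3 balanced groups,
20% DE genes, lfc_scale 2, θ = 10, depths in [0.5, 2] — are desk-scale
stand-ins for real datasets: large enough for group structure to be
recoverable, small enough that every test re-simulates from scratch.
Group labels, fold changes and size factors are all echoed into metadata
so tests assert on generator internals rather than re-deriving them.

`simulate_ortholog_table` consumes features in order (one2one block,
one2many block with fan-out uniform on [2, max_fanout], complete-bipartite
many2many blocks, unmapped block); targets are uppercase transforms with
collision-free suffixes. `simulate_pdx` stacks a human and a mouse block
over shared cells, reusing the mouse table's human targets as human
feature names so the merge path actually collides. `simulate_marker_groups`
builds groups separable *only* through private high-mean marker blocks:
removing the blocks that distinguish two groups provably merges them,
which is how the "conversion can destroy structure" fixtures are
constructed (removing just one group's block is not enough — that group
remains identifiable by the absence of everyone else's markers).

What the generators do **not** emulate: spatial autocorrelation, batch
effects, doublets, ambient RNA, library-level zero inflation beyond NB,
or realistic gene-gene correlation. Passing tests therefore demonstrate
algorithmic correctness of the conversion and its accounting on
NB-structured data, not biological fidelity on any real dataset.

## Problem sizes and numerical choices

Tests and the acceptance script run at deliberately small scales chosen
as the package's own verification sizes: ~200 random conversion instances
(≤ 50 genes × 20 observations) against the dense reference, 150-cell
clustering fixtures, 200 ARI null replicates at n = 1000, 520 Rand-index
enumeration fixtures. All randomness flows through explicit seeds
(`numpy.random.default_rng`; child seeds via `SeedSequence`). Integer
arithmetic is exact end-to-end in conversion and conservation checks;
floating-point comparisons elsewhere use pytest's default approx
tolerances. Degenerate inputs are defined rather than accidental:
empty-total matrices report efficiency 0 with a warning, a policy that
drops every group yields a zero-feature matrix (not an error), and "no
feature has any ortholog" is the one hard conversion error, carrying the
zero mapping rate.

## Known limitations

- No expression-aware paralog disambiguation: `max_total` is a global
  row-total rule, not a per-cluster or correlation-based assignment.
- No normalization, batch correction or read-level xenograft
  deconvolution; the PDX split is purely feature-namespace based.
- `.RDS` Seurat containers are not parsed; the documented interop path is
  export to MTX/h5ad.
- `fetch-table` is a thin stub that refuses to run offline by design; the
  supported offline path is a pre-exported homolog TSV.
- The case heuristic misclassifies genes whose symbols break the
  uppercase/Title-case convention (e.g. human orfs written lowercase);
  prefix or table-based detection should be preferred whenever available.
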