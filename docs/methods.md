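# Methods

This note documents the models and procedures implemented in `crossnet`,
the defaults that matter, the design choices made where the design was
genuinely open, and what the synthetic fixtures do and do not establish.

## Module-definition grammar and alternatives

A KEGG module DEFINITION couples KO terms four ways: consecutive pathway
steps (top-level whitespace, logical AND), members of a molecular complex
(`+`, AND), interchangeable options for one step (`,`, OR), and optional
components (`-`). Operator precedence, loosest to tightest, is space <
comma < `+`/`-`, so `A B,C` parses as "A, then (B or C)". Parsing is
recursive descent over a token stream; every leaf must be a KO identifier
(`K` + five digits) or the gap token `--`, and parse errors name the
offending position.

An *alternative* is produced by choosing exactly one option per step and
taking the union of the chosen options' required KOs. Within an option,
complex members are all required; optional members are excluded entirely —
they are never required and never counted as missing, since an optional
subunit cannot block completion. The gap token denotes a step KEGG leaves
uncharacterized; it is satisfied by any genome and contributes no KOs,
because requiring it would make such modules permanently uncompletable.
An option that becomes empty after optional-drop remains a valid (smaller)
choice. Duplicate KO sets arising from different choice tuples are
collapsed; the surviving record keeps one choice tuple as provenance.

Enumeration cost is bounded before expansion by the product of per-step
option counts; the default cap is 50,000 (the largest module encountered
in practice, glycolysis, has 13,440 alternatives), configurable per call.
Multi-line DEFINITION fields in KEGG flat files are joined with a single
space before parsing.

A genome *completes* a module iff it contains every KO of at least one
alternative. Completion is a plain subset test and is checked in tests
against an independent exhaustive expansion oracle.

## Pathway complementarity

For an ordered (beneficiary, donor) pair and each module the beneficiary
does not complete, each alternative `A` yields a complement
`missing = A \ beneficiary` iff `missing` is nonempty and fully contained
in the donor's KOs. Choices made here:

* **All qualifying alternatives are reported**, not only minimal missing
  sets; `minimal_complements` (CLI `--minimal-only`) additionally drops
  any complement whose missing set strictly contains another's for the
  same (beneficiary, donor, module) group. Statistics are computed on
  unique (module, missing-set) pairs.
* **No minimum beneficiary coverage** of the module is required by
  default; `--min-covered-fraction` exposes an optional threshold.
* **Complex members are ordinary KOs**: a donor may supply a single
  subunit of a beneficiary complex. The complement definition operates on
  KO sets uniformly, and enforcing complex atomicity would only remove
  predictions that are already upper bounds.
* `max_missing` is unbounded by default; the statistics report also
  tabulates the split at >4 missing KOs, a practical plausibility cut
  (the more KOs must be transferred, the less likely the complementation).

KEGG map URLs place one `KO%09color` token per KO on a `show_pathway`
query, donor KOs in blue-green (`#00b8b8`), beneficiary KOs in red, sorted
for byte-identical reproducibility.

Limitations: complementarity is genome-potential only. No check is made
that the relevant metabolites can be excreted or imported, that
transporters exist, or that the completed pathway is active under any
given condition; predictions are upper bounds on potential interactions.

## Seed sets and seed scores

Reactions induce a directed compound graph: an edge from every substrate
to every product, both directions for reversible reactions, self-loops
dropped, parallel edges collapsed. Graph semantics are deliberately simple
substrate→product reachability rather than an AND-hypergraph firing rule,
consistent with the classical reverse-ecology seed-set formulation.

The graph's condensation into strongly connected components is a DAG; the
*seed set* is the union of all source SCCs (zero in-degree). Seeds in an
interdependent SCC of size *k* each get confidence *C* = 1/*k*, so
confidences sum to one per source SCC; an isolated compound is a seed with
*C* = 1. The 1/*k* reading (rather than *k*) is what keeps the
competition index inside [0,1] and matches the original seed-set
formulation. The non-seed set is simply compounds minus seeds.

Normalization before graph construction, both configurable:

* compartment suffixes matching `_[a-zA-Z]\d*$` (ModelSEED-style `_c0`,
  `_e0`) are stripped, so a compound is one node regardless of
  compartment;
* pseudo-reactions matching `^(bio\d*|biomass.*|EX_.*|SK_.*|DM_.*)$` are
  dropped (biomass and exchange stubs carry no biochemistry);
* an optional currency-metabolite exclusion list can remove compounds
  entirely (none are excluded by default).

The indices for an ordered pair (A beneficiary, B donor):

* MI_Complementarity = |Seeds_A ∩ NonSeeds_B| / |Seeds_A| — the fraction
  of A's requirements B can make on its own; an upper bound on
  cross-feeding.
* MI_Competition = Σ_{shared seeds} C_A / Σ_{all seeds of A} C_A — both
  numerator and denominator weighted by the *beneficiary-side*
  confidences. Asymmetry in both indices is expected and preserved.

Both are undefined (raise) for an empty seed set. Seed *complements*
report the actual compounds behind the complementarity index, filtered to
a module-linked whitelist from the compound-namespace mapping and grouped
per KEGG map; compounds lacking a KEGG translation still count in the
indices (which are defined on raw seed sets) but are not listed.

Limitations: seed sets are environment-free — no growth medium
conditions them — and no essentiality check is made, so seeds that are
dispensable in rich media inflate the cross-feeding estimate. Different
reconstruction pipelines give different networks and hence different seed
sets.

## Taxon-to-genome mapping

GTDB- and Silva-style lineages are matched exactly after normalization
(rank prefixes `d__` … `s__` stripped, case-insensitive, empty trailing
ranks removed). Any other naming scheme falls back to fuzzy matching of
the deepest taxon name against the genome index using normalized
Levenshtein similarity, `100 · (1 − d/max(|a|,|b|))` with `d` the plain
edit distance (computed by edlib, verified in tests against a DP oracle).
The acceptance threshold defaults to 90 — high, to keep false assignments
out. Equal-score ties resolve to the lexicographically smallest name, a
deterministic but biologically arbitrary rule. Genome assignment is gated
at species or strain level, inferred from the deepest populated rank (7
unprefixed fields or a bare binomial count as species); one node may map
to several representative genomes, and all ordered genome combinations are
evaluated per edge.

## Annotated network

Co-occurrence edges are copied unchanged; the sign of the weight is stored
as an attribute (`positive co-occurrence` / `mutual exclusion`), not as a
separate edge type. Per associated node pair and direction, a single
directed complementarity edge (donor = source, beneficiary = target) is
added iff at least one genome combination has a pathway or seed
complement; the edge carries the per-genome-pair sub-tables and seed
scores. Re-annotation with identical inputs reproduces the same edge set
(fixed edge keys make the operation idempotent), and annotation never
removes or reweights an input edge.

CX2 output uses a documented minimal aspect layout (`CXVersion`,
`networkAttributes`, `attributeDeclarations`, `nodes`, `edges`, `status`)
with complement tables serialized as JSON strings in edge attributes, and
one string column per trait on nodes; the same information is exported as
flat node/edge TSVs.

## Cluster-trait enrichment

Per (cluster, trait): `k` trait-positive of `n` annotated cluster nodes
against `K` of `N` in the annotated background, tested with one-sided
hypergeometric tails in both directions — enrichment `P[X ≥ k]`, depletion
`P[X ≤ k]`. One-sided tails (rather than a two-sided Fisher test) keep the
direction of every finding explicit. Nodes with an unknown call are
excluded per test (unknown is distinct from absent); traits positive in
zero background nodes are skipped with a logged reason. All cluster ×
trait × direction p-values are pooled into a single Benjamini–Hochberg
family, matching a single FDR statement over one findings table. The BH
step-up is delegated to statsmodels and verified in tests against the
hand-evaluated formula; the hypergeometric tails (scipy) are verified
against exhaustive combinatorial sums for every background size N ≤ 25.

## Synthetic fixtures

All generators draw from one explicitly seeded `numpy.random.Generator`
per call (PCG64); identical parameters and seed give byte-identical
output files. What they emulate, and what they do not:

* **Module definitions** — random steps/options/complexes/optionals with
  the planted alternative count equal to the product of per-step option
  counts. KO ids are minted uniquely per definition so options never
  collide and the planted count is exact; real KEGG definitions reuse KOs
  across modules and nest more deeply, which the parser handles but the
  generator does not produce.
* **Genome pairs** — beneficiary = alternative minus k random KOs, donor
  = those k plus decoys from a disjoint id range, so the planted
  complement is recoverable exactly and decoys cannot complete anything.
* **Metabolic networks** — planted SCCs (reversible chains or directed
  cycles) wired along a forward-directed DAG; planted seeds are the
  source-SCC members with confidence 1/size. Real genome-scale networks
  have hub metabolites and far larger SCCs; fixture sizes default to ≤
  ~50 compounds (≤ 200 in the recovery checks).
* **Communities** — trait *i* elevated (default probability 0.8) in
  cluster *i* versus background 0.2, denser positive-weight edges within
  clusters; default study sizes are 100 nodes and 2 clusters for power
  checks. Passing tests on these fixtures shows the statistics are
  calibrated and the pipeline recovers planted structure; it does not
  show that predictions are accurate for real communities, where trait
  predictions, genome assignments, and network inference all carry their
  own error.

The full fixture directory (`crossnet simulate`) chains everything into a
12-taxon, 4-module, 2-cluster community with planted complements, seeds,
and enrichments recorded in `truth.json`. The reaction-TSV writer adds a
`#compounds:` header line enumerating the compound universe so isolated
compounds (seeds with no incident reaction) survive write/read round
trips; the reader treats the line as optional.

## Numerical choices and degenerate inputs

* Alternative enumeration and all set operations are exact (frozensets).
* MI_Competition clamps at 1.0 to absorb float accumulation of 1/k terms.
* Empty module definition, unbalanced parentheses, non-KO tokens, empty
  metabolic networks, unknown compounds in reactions, duplicate reaction
  ids, p-values outside [0,1], undeclared traits, unknown taxonomy
  schemes, and complements referencing unmapped genomes all raise with
  specific messages rather than degrading silently.
* All emitted tables and URLs sort their members, so outputs are
  deterministic byte-for-byte.

## Problem sizes used in validation

The automated validation (`scripts/acceptance.py`, a few seconds on one
CPU) uses 200 random definitions for enumeration checks, 500 planted
(beneficiary, donor, module) triples for complement recovery, 100 planted
networks of up to 200 compounds for seed recovery, 10 networks for the
index identities, and 100 replicates each of signal (effect 0.8) and null
(0.2) 100-node communities for enrichment power and false-call rate.
These sizes give exact-recovery checks full coverage of the generator
families while keeping runs interactive.
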