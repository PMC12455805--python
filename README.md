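# crossnet

Co-occurrence networks inferred from microbiome sequencing data say *which*
taxa associate, but not *why*. `crossnet` annotates such networks with
mechanistic hypotheses derived purely from genome content: which member of
an associated pair could feed the other, through which pathway, and with
which metabolites — plus phenotypic trait attributes per taxon and
cluster-level trait enrichment statistics. It is a library with a thin CLI,
and it runs end to end on synthetic fixtures with no database download.

## What it computes

**Pathway complementarity.** A KEGG module's DEFINITION is a logical
expression over KO terms (spaces = consecutive steps, commas = alternative
options for a step, `+` = complex members, `-` = optional members). An
*alternative* is a KO set realizing every step in exactly one way; a genome
*completes* a module iff it carries all KOs of at least one alternative.
For an ordered (beneficiary, donor) genome pair, every alternative *A* of
every module the beneficiary does not complete yields a complement

&nbsp;&nbsp;&nbsp;&nbsp;*missing* = *A* \ KOs(beneficiary),&nbsp;
emitted iff *missing* ≠ ∅ and *missing* ⊆ KOs(donor),

i.e. the donor carries exactly the KOs the beneficiary lacks. Complements
are deduplicated on (module, missing set) and rendered as colored KEGG map
URLs (donor contribution in blue-green, beneficiary KOs in red).

**Seed complementarity.** From each genome's metabolic network (reaction
list or minimal SBML) the directed compound graph is built (substrate →
product per reaction, both directions if reversible) and condensed into
strongly connected components. Compounds in source SCCs are the *seed set*
— nutrients the organism needs exogenously — each with confidence
*C* = 1/|SCC|; everything else is the *non-seed set*, what the network
makes on its own. Two indices summarize an ordered pair (A beneficiary,
B donor):

&nbsp;&nbsp;&nbsp;&nbsp;MI_Complementarity(A,B) = |Seeds_A ∩ NonSeeds_B| / |Seeds_A|
&nbsp;&nbsp;&nbsp;&nbsp;MI_Competition(A,B) = Σ_{c ∈ Seeds_A ∩ Seeds_B} C_A(c) / Σ_{c ∈ Seeds_A} C_A(c)

both in [0,1], with MI_Complementarity(A,A) = 0 and MI_Competition(A,A) = 1.
The concrete cross-feedable compounds (beneficiary seeds ∩ donor
non-seeds, restricted to KEGG-module-linked compounds) are listed per KEGG
map.

**Network assembly.** Taxa are mapped to genomes by exact lineage match
(GTDB/Silva dialects) or Levenshtein fuzzy matching (0–100 similarity,
threshold 90) for other naming schemes; only species/strain-level nodes are
mapped. Co-occurrence edges are preserved untouched; for each associated
pair with complements, up to two *directed* complementarity edges are added
(donor = source, beneficiary = target), one per direction, carrying
per-genome-pair sub-tables. Output is CX2 JSON (Cytoscape-loadable) plus
flat TSV tables.

**Trait enrichment.** Each (cluster, trait) cell is tested with one-sided
hypergeometric tails (enrichment: P[X ≥ k]; depletion: P[X ≤ k]) against
the annotated background, with Benjamini–Hochberg FDR control over the full
cluster × trait × direction family.

## Worked example

Generate a synthetic community with planted ground truth, annotate it, and
test cluster enrichment:

```bash
crossnet simulate --out demo --seed 7
# demo: 9 planted complements, 2 planted enrichments

crossnet annotate \
    --network demo/network.tsv --node-taxonomy demo/node_taxonomy.tsv \
    --ko-table demo/genomes.tsv --modules demo/modules.tsv \
    --reactions-dir demo/reactions --mapping demo/mapping.tsv \
    --traits demo/traits.tsv --clusters demo/clusters.tsv \
    --genome-index demo/genome_index.tsv --out demo_out
```

which logs

```
12/12 nodes mapped to genomes
pathway complements: {'pairwise_pathway_complementarities': 14,
 'unique_complements': 14, 'unique_complements_gt4_kos': 6, 'modules': 4}
seed scores for 16 ordered pairs, 7 seed complements
annotated network written to demo_out (8 complementarity edges)
```

All 12 taxa carry species-level lineages present in the genome index, so
all map. The 14 pairwise complements include the 9 planted ones plus
incidental ones among the donated KO sets; 6 of the 14 unique (module,
missing-set) pairs would require more than 4 KOs from the donor. A row of
`demo_out/pathway_complements.tsv` reads

```
G010  G005  M00002  synthetic  K04001;K04002  K04001;K04002;K04003;K04004  https://www.kegg.jp/...
```

meaning genome G005 supplies the two KOs that complete the listed
alternative of module M00002 in genome G010, with the map URL coloring
donor KOs blue-green and beneficiary KOs red. Enrichment on the planted
clusters:

```bash
crossnet enrich --traits demo/node_traits.tsv --clusters demo/clusters.tsv \
    --alpha 0.1 --out demo_out/enrichment.tsv
# 2/20 tests significant at q < 0.1
# c0  trait00  enriched  q=0.0758
# c1  trait00  depleted  q=0.0758
```

With only 12 nodes the planted signal for `trait00` in cluster `c0` is
detected (and its mirror-image depletion in `c1`); larger communities give
q-values far below 0.05 (see `tests/test_acceptance.py`).

A YAML config mirroring every `annotate` flag can be passed with
`--config`; `crossnet module-stats` reports per-module alternative counts;
`crossnet fetch-modules --fetch` optionally retrieves real KEGG DEFINITION
strings over REST (the only operation that touches the network, and only
when explicitly requested).

## Layout

```
src/crossnet/
  kegg_modules.py   module-definition grammar, alternative enumeration
  complementarity.py pathway complements, dedup, KEGG map URLs
  seeds.py          compound graph, SCC condensation, seed sets
  seed_scores.py    MI indices, seed complements
  taxonomy.py       exact/fuzzy taxon-to-genome mapping
  annotate.py       annotated-network assembly, trait filters
  enrichment.py     hypergeometric cluster-trait tests, BH
  fixtures.py       seeded generators with planted truth
  io.py             TSV/SBML/GraphML/CX2 readers and writers
  cli.py            annotate / enrich / simulate / module-stats / fetch-modules
```

See `docs/methods.md` for the modeling assumptions, parameter defaults,
and known limitations.
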