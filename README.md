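# meiodiv

Phylogenetic-placement taxonomy assignment and diversity analysis for
meiofauna metabarcoding surveys.

Marine meiofauna — the animals small enough to pass a 1 mm sieve — are
routinely profiled by metabarcoding: a marker gene (18S V1–V2, COI
mini-barcode) is amplified from bulk sediment, sequenced, and resolved into
exact-sequence-variant OTUs. Two analysis problems follow. First, which
species is each OTU? Generic classifiers stall at coarse ranks for poorly
databased groups, so the OTUs of interest are placed onto curated reference
phylogenies (PPlacer-style jplace output) and assigned from the placement
likelihood weights. Second, how do communities differ between sampling
localities? That is classical alpha/beta diversity: Chao1 richness,
rarefaction, Jaccard distances, PCoA ordination and ANOSIM permutation
tests.

`meiodiv` implements both halves as a tested, reusable Python library for
ecologists working with OTU tables, jplace files and taxon-labelled
reference trees. A synthetic-data module generates every input with known
ground truth, so the whole pipeline is testable without sequencing data.

## The assignment rule

Each query OTU arrives as placements on the numbered edges of a reference
tree, each with a like-weight ratio (LWR) `w_i ∈ [0,1]`, `Σ w_i ≤ 1`. With
support threshold `t = 0.90`:

1. **Single placement** — if `max_i w_i ≥ t`, assign the most specific
   taxon shared by all reference leaves below that edge.
2. **Cumulative clade mass** — otherwise scan candidate taxa from species
   upward. A taxon qualifies only if its reference leaves form a
   monophyletic clade; its captured mass is `Σ w_i` over edges inside the
   clade plus its stem edge. The most specific monophyletic taxon with
   captured mass `≥ t` wins; exact ties escalate one rank; if none
   qualifies the query stays unassigned.

Non-monophyletic taxa are never assignable at their own rank — support
escalates to the nearest monophyletic ancestor.

## The diversity statistics

* Chao1 (bias-corrected): `S_chao1 = S_obs + F1(F1−1) / (2(F2+1))` from
  singleton and doubleton counts; classic form available.
* Rarefaction without replacement: multivariate-hypergeometric subsampling
  to a common depth, plus the closed-form expectation
  `E[S] = Σ_i (1 − C(N−n_i, d)/C(N, d))`.
* Jaccard distance on presence/absence; classical PCoA (double-centered
  `−D²/2`, eigendecomposition); one-way ANOVA on per-sample alpha values.
* ANOSIM: `R = (r̄_between − r̄_within) / (n(n−1)/4)` on average-ranked
  distances, permutation p-value `p = (1 + #{R_perm ≥ R_obs}) / (1 + 999)`,
  global and pairwise.

## Worked example

```python
from meiodiv import (sim_reference_tree, sim_placements, assign_all)

tree = sim_reference_tree(n_species=20, leaves_per_species=3, seed=7)
pset, truth = sim_placements(tree, n_queries=200, concentration=0.95,
                             noise=0.05, seed=8)
assignments = assign_all(pset, tree, threshold=0.90)
```

Running `python examples/placement_assignment.py` prints:

```
queries assigned: 200
decision rules used: {'cumulative': 200}
true species recovered: 200/200 (100.0%)
```

With 95% of the likelihood weight spread across a species clade no single
edge reaches 0.90, so every query is assigned by the cumulative rule — and
every one recovers its true species. `examples/diversity_analysis.py` runs
the alpha/beta workflow on a simulated five-locality survey (its global
ANOSIM prints `R = 1.000, p = 0.001` under strong site effects), and
`examples/community_composition.py` re-derives printed survey percentages
from the bundled composition tables:

```
18S dataset: 3615 OTUs, 9691423 reads
  Metazoa: 1639 OTUs = 45%
  SAR: 1313 OTUs = 36%
  Unknown: 247 OTUs = 6.8%
```

A thin CLI mirrors the library (`meiodiv validate | filter-samples |
assign | species-table | alpha | beta | summarize | shared | divergence |
simulate`); run `meiodiv --help`.

## Layout

```
src/meiodiv/
  io.py         OTU tables, metadata, taxonomy, low-yield sample filter
  jplace.py     edge-numbered trees, jplace reading/writing
  placement.py  edge-taxonomy index, monophyly, the assignment rules
  diversity.py  Chao1, rarefaction, ANOVA, Jaccard, PCoA, ANOSIM
  summary.py    rank aggregation, percentages, shared OTUs, divergence
  simulate.py   reference-tree / placement / community generators
  datasets.py   bundled printed survey tables (TSV)
  cli.py        thin command-line veneer
docs/methods.md   model and design notes
examples/         one narrative script per capability
```
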