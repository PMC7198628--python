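# Methods

## Placement-based taxonomy assignment

A query OTU's evidence is a set of placements on an edge-numbered,
taxon-labelled reference tree, each carrying a like-weight ratio (LWR):
the normalized share of placement likelihood the query puts on that edge.
Per query the LWRs sum to at most 1 (placement tools may truncate the
tail; the parser enforces `Σ ≤ 1 + 1e-6`).

The decision procedure, at support threshold `t` (default 0.90, domain
[0.5, 1] so that no two disjoint clades can both strictly exceed it):

1. **Single-placement rule.** If one placement alone carries LWR ≥ t, the
   query is assigned the most specific taxon shared by every reference
   leaf below that edge, at that taxon's rank. An edge whose leaves share
   no taxon at any rank cannot assign; evaluation falls through to rule 2.
2. **Cumulative rule.** Candidate taxa are scanned most-specific rank
   first (the rank ladder is derived from the lineage records, so
   whatever ladder the reference database uses is honoured). A taxon is
   assignable only if its leaves form exactly one clade on the rooted
   tree (a single reference leaf counts as monophyletic). Its captured
   mass is the summed LWR over edges strictly inside the clade **plus the
   clade's stem edge** — a placement on the branch leading into a species
   clade is evidence for that species. The most specific qualifying taxon
   with captured mass ≥ t is assigned; if two taxa at one rank tie
   exactly (possible only through shared stem edges), assignment
   escalates one rank rather than guessing. If nothing qualifies the
   query is reported unassigned together with the best captured mass.

Design choices made where the procedure was genuinely open:

* LWR is used as the support measure for both rules (it is the placement
  tools' primary per-edge output); the field read is configurable through
  the jplace `fields` declaration, which is mapped by name, never by
  position.
* The cumulative rule is applied bottom-up per rank rather than to a
  pre-chosen clade, which makes the assigned rank monotone in the
  threshold: raising t can only coarsen an assignment. This is exercised
  as a property test over random placement sets.
* Non-monophyletic reference taxa never assign at their own rank;
  support escalates to the nearest monophyletic ancestor. This is the
  literal reading of the "single monophyletic clade" requirement and
  protects against reference databases with polyphyletic genera.

The edge-taxonomy index precomputes, once per tree, each edge's leaf set
and shared taxon plus each monophyletic taxon's capture edge set, so
batch assignment is linear in placements per query.

## Diversity statistics

All statistics are implemented in the package; scikit-bio and scipy
equivalents serve as independent cross-checks in the test suite only.

* **Chao1** (bias-corrected default): `S_obs + F1(F1−1)/(2(F2+1))`. The
  classic form `S_obs + F1²/(2F2)` is available by flag and falls back to
  the bias-corrected form when F2 = 0, where it is undefined.
* **Rarefaction without replacement** draws a multivariate hypergeometric
  subsample summing exactly to the requested depth; a depth exceeding the
  sample total is an error, never a silent drop. The closed-form
  expectation `E[S] = Σ_i (1 − C(N−n_i,d)/C(N,d))` is computed in exact
  rational arithmetic up to N = 2000 and with log-gamma beyond; the
  Monte-Carlo mean is required to match it within three standard errors.
* **One-way ANOVA** on per-sample alpha values grouped by locality; both
  Chao1 and observed richness are supported as the response. Zero
  within-group variance with zero between-group variance is undefined and
  raises.
* **Jaccard distance** is computed on presence (count ≥ 1) and is
  therefore invariant to read-count scaling; two empty samples are at
  distance 0.
* **PCoA** is classical scaling: double-center `−D²/2`, eigendecompose,
  scale eigenvectors by sqrt of the positive eigenvalues. Negative
  eigenvalues (non-Euclidean input) are reported but not corrected —
  no Lingoes/Cailliez — and their axes are dropped. On
  Euclidean-embeddable input the coordinates reproduce all pairwise
  distances to 1e-8 relative error.
* **ANOSIM** ranks the `M = n(n−1)/2` pairwise distances with average
  ranks on ties (Jaccard on sparse tables ties heavily) and computes
  `R = (r̄_B − r̄_W)/(M/2)`, which is confined to [−1, 1]. The p-value
  permutes group labels with the add-one convention
  `p = (1 + #{R_perm ≥ R_obs})/(1 + n_perm)`, so the smallest attainable
  p is `1/(n_perm+1)`; `n_permutations="all"` enumerates every label
  permutation for hand-scale exact checks. Pairwise tests run on each
  pair's sub-matrix and report raw p-values (no multiplicity
  adjustment).
* For beta diversity the intended workflow is a **single rarefied draw**
  per sample with a recorded seed, matching common practice; averaging
  over draws is possible by calling `rarefy_table` repeatedly.

## Community summaries

Aggregation to a rank counts an OTU toward a locality iff it has ≥ 1 read
in ≥ 1 of the locality's samples; the Total column counts distinct OTUs
once, so per-locality OTU counts need not sum to it, while read totals
sum exactly. Presence is evaluated after the low-yield sample exclusion
(default cutoff 1000 total reads, configurable) but before rarefaction:
composition describes the full yield, rarefaction is reserved for
diversity comparisons. Printed-style percentages follow a mixed-precision
rule — integer at ≥ 10%, one decimal at 1–10%, two decimals below 1%
(half-up) — with the raw ratios always returned for callers who need
other conventions. Pairwise sequence divergence removes, per pair, every
column where either sequence has anything outside A/C/G/T (gaps and
ambiguity codes alike) and reports both the count and the percentage of
the remaining columns.

## Synthetic data

The generators are pure functions of their seed and produce the
statistical structure the analyses assume — no sequence-level simulation
(no read errors, chimeras or PCR bias); placement uncertainty is modelled
directly at the LWR level.

* `sim_reference_tree` joins leaves into species, species into genera,
  genera into families by random sequential binary joins with
  exponential branch lengths, so every labelled taxon is monophyletic by
  construction and lineages are nested (family → genus → species).
* `sim_placements` draws each query's true species uniformly, spreads
  `concentration` LWR mass over the species clade's edges with uniform
  Dirichlet weights (the least informative choice; it affects only test
  difficulty), scatters `noise` over up to three outside edges and
  leaves the remainder unreported. A congeneric mode splits the mass
  across two species of one genus, making the genus the recorded truth.
* `sim_community` models log-normal base abundances (σ = 1.5 by default,
  which produces realistic singleton/doubleton tails for Chao1),
  per-locality log-normal multiplicative effects with standard deviation
  `site_effect_sd`, and multinomial per-sample counts at fixed depth.
  `site_effect_sd = 0` makes all samples exchangeable — the null used to
  calibrate ANOSIM's type-I error; the default 2.0 produces the strong
  between-site structuring characteristic of surveyed sediment
  communities. The default design is five localities with 3/3/3/2/2
  replicates (13 samples), depth 50,000 reads and 500 OTUs.

What the simulations do **not** capture: taxonomic autocorrelation of
abundances, overdispersion beyond the multinomial, uneven reference
coverage, and alignment/placement error models. Passing recovery and
calibration tests therefore demonstrates correctness of the decision
rules and statistics, not field-data robustness.

## Problem sizes and numerical notes

Test and acceptance experiments run at desk scale: recovery on 20
species × 3 leaves with 500 queries; monotonicity over 1000 random
placement sets at thresholds {0.5, 0.7, 0.9, 0.99}; ANOSIM calibration
over 200 exchangeable datasets (13 samples, 300 OTUs, depth 5000, 999
permutations) expecting a 5% ± 2% rejection rate at α = 0.05, and power
over 60 datasets at `site_effect_sd = 2.0` expecting R > 0.5 in ≥ 95%.
Depth and OTU count do not enter the null distribution of the rank-based
statistic, so the calibration result is insensitive to those choices.
Ties in capture masses and permutation-count comparisons use a 1e-12
tolerance; distance matrices are validated symmetric and hollow at
1e-12; PCoA's positive-eigenvalue cutoff is relative (1e-10 of the
leading eigenvalue).

## Bundled survey tables

`datasets.py` ships the motivating survey's printed composition tables as
TSV cells (per-locality OTU/read counts by higher group, metazoan phylum
and assigned species, the shared-OTU list, and the read-yield pipeline
totals). They are stored exactly as printed; two printed quirks are
deliberately preserved rather than repaired (one species-summary row
whose overall OTU count exceeds its per-site sum, and one "other phyla"
read percentage that cannot be re-derived from the table's own cells).
The tests and the acceptance script recompute every reproducible
percentage and derived count from these cells.

## Known limitations

* jplace v1 documents that encode per-pquery naming in exotic ways
  beyond `n`/`nm` are rejected rather than guessed.
* The exhaustive ANOSIM mode enumerates all `n!` label permutations and
  is intended for n ≤ 8.
* PCoA returns no axes for an all-zero distance matrix (every
  eigenvalue is zero); callers ordinating degenerate data should check
  `coordinates.shape[1]`.
* The exact rarefaction expectation switches to log-gamma above
  N = 2000, where it is accurate to ~1e-12 relative, not exact.
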