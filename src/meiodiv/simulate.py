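"""Synthetic inputs with the statistical structure the analyses assume.

Three generators, all pure functions of their seed:

* :func:`sim_reference_tree` — a labelled reference tree in which species
  are monophyletic leaf clusters nested inside genera and families, built
  by random binary joins level by level (a Yule-style backbone).
* :func:`sim_placements` — jplace-style placement sets with recorded true
  taxa: a controllable share of like-weight-ratio mass (Dirichlet-spread)
  falls inside the true species clade, an optional noise share on random
  outside edges, the remainder unreported.
* :func:`sim_community` — multi-locality OTU count tables: log-normal base
  abundances, per-locality log-normal multiplicative effects, multinomial
  per-sample counts at fixed depth.  With ``site_effect_sd = 0`` all
  samples are exchangeable (the null for ANOSIM calibration).

The default community design mirrors the motivating survey: five
localities with two or three replicates each, thirteen samples in total.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .io import OtuTable, SampleMetadata, ValidationError
from .jplace import Placement, PlacementSet, ReferenceTree
from .placement import index_edges

__all__ = [
    "SimTruth",
    "CommunitySimSpec",
    "sim_reference_tree",
    "sim_placements",
    "sim_community",
]


@dataclass
class SimTruth:
    """Ground truth for simulated placements: query -> (true taxon, rank)."""

    truth: dict[str, tuple[str, str]]
    params: dict[str, float | int | str] = field(default_factory=dict)


def _join_random(nodes: list[dendropy.Node], rng: np.random.Generator,
                 scale: float) -> dendropy.Node:
    """Random sequential binary joins; returns the root of the joined tree."""
    nodes = list(nodes)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(int(j))
        a = nodes.pop(int(i))
        parent = dendropy.Node()
        parent.add_child(a)
        parent.add_child(b)
        a.edge.length = float(rng.exponential(scale)) + 1e-3
        b.edge.length = float(rng.exponential(scale)) + 1e-3
        nodes.append(parent)
    return nodes[0]


def sim_reference_tree(
    n_species: int,
    leaves_per_species: int = 3,
    genera: int | None = None,
    seed: int = 0,
) -> ReferenceTree:
    """Simulate a reference tree with nested family/genus/species labels.

    Species, genus and family clades are monophyletic by construction:
    each species' leaves are joined first, then species within a genus,
    genera within a family, and families at the root.
    """
    if n_species < 2:
        raise ValidationError("need at least 2 species")
    if leaves_per_species < 1:
        raise ValidationError("need at least 1 leaf per species")
    rng = np.random.default_rng(seed)
    n_genera = genera if genera is not None else max(2, (n_species + 2) // 3)
    n_genera = min(n_genera, n_species)
    n_families = max(1, (n_genera + 2) // 3)

    taxon_ns = dendropy.TaxonNamespace()
    lineages: dict[str, list[tuple[str, str]]] = {}
    genus_roots: dict[int, list[dendropy.Node]] = {g: [] for g in range(n_genera)}
    for s in range(n_species):
        g = s % n_genera
        f = g % n_families
        sp = f"Sp{s + 1:03d}"
        lineage = [
            ("family", f"Fam{f + 1:02d}"),
            ("genus", f"Gen{g + 1:02d}"),
            ("species", sp),
        ]
        leaf_nodes = []
        for k in range(leaves_per_species):
            label = f"{sp}_{k + 1}"
            taxon = taxon_ns.new_taxon(label)
            node = dendropy.Node(taxon=taxon)
            node.edge.length = float(rng.exponential(0.02)) + 1e-3
            leaf_nodes.append(node)
            lineages[label] = list(lineage)
        sp_root = leaf_nodes[0] if len(leaf_nodes) == 1 else _join_random(
            leaf_nodes, rng, 0.02)
        genus_roots[g].append(sp_root)

    family_roots: dict[int, list[dendropy.Node]] = {f: [] for f in range(n_families)}
    for g, roots in genus_roots.items():
        gr = roots[0] if len(roots) == 1 else _join_random(roots, rng, 0.1)
        family_roots[g % n_families].append(gr)
    top = []
    for _f, roots in family_roots.items():
        top.append(roots[0] if len(roots) == 1 else _join_random(roots, rng, 0.2))
    root = top[0] if len(top) == 1 else _join_random(top, rng, 0.5)
    root.edge.length = 0.0

    tree = dendropy.Tree(taxon_namespace=taxon_ns)
    tree.seed_node = root
    edge_map = {i: e for i, e in enumerate(tree.postorder_edge_iter())}
    rtree = ReferenceTree(tree=tree, lineages=lineages, edge_map=edge_map)
    return rtree


def sim_placements(
    tree: ReferenceTree,
    n_queries: int,
    concentration: float = 0.95,
    noise: float = 0.05,
    seed: int = 0,
    congeneric: bool = False,
) -> tuple[PlacementSet, SimTruth]:
    """Simulate placements with known truth.

    For each query a true species is drawn uniformly; LWR mass
    ``concentration`` is Dirichlet-spread over the edges of the true
    species clade (stem included), ``noise`` over up to three random edges
    outside it, and the remainder left unreported, so per-query LWR sums
    never exceed 1.  With ``congeneric=True`` the concentration is split
    across two species of one genus and the recorded truth is the genus.
    """
    if not 0 < concentration <= 1:
        raise ValidationError("concentration must be in (0, 1]")
    if noise < 0 or concentration + noise > 1 + 1e-9:
        raise ValidationError("need concentration + noise <= 1")
    rng = np.random.default_rng(seed)
    index = index_edges(tree)
    species = sorted(k for k in index.clade_edges if k[1] == "species")
    if not species:
        raise ValidationError("tree has no species clades")
    all_edges = set(index.edge_leaves)

    genus_species: dict[str, list[tuple[str, str]]] = {}
    if congeneric:
        for leaf, lin in tree.lineages.items():
            ranks = dict(lin)
            key = ranks.get("genus")
            sp = (ranks.get("species"), "species")
            if key and sp not in genus_species.get(key, []):
                genus_species.setdefault(key, []).append(sp)
        genus_species = {g: sorted(sps) for g, sps in genus_species.items()
                         if len(sps) >= 2 and index.monophyletic.get((g, "genus"))}
        if not genus_species:
            raise ValidationError("no monophyletic genus with two species")

    placements: dict[str, list[Placement]] = {}
    truth: dict[str, tuple[str, str]] = {}
    for i in range(n_queries):
        qid = f"query{i + 1:05d}"
        if congeneric:
            genus = sorted(genus_species)[int(rng.integers(len(genus_species)))]
            sp_a, sp_b = [genus_species[genus][int(k)] for k in
                          rng.choice(len(genus_species[genus]), 2, replace=False)]
            targets = [(sp_a, concentration / 2), (sp_b, concentration / 2)]
            truth[qid] = (genus, "genus")
        else:
            sp = species[int(rng.integers(len(species)))]
            targets = [(sp, concentration)]
            truth[qid] = (sp[0], "species")
        plist: list[Placement] = []
        used: set[int] = set()
        for sp_key, mass in targets:
            edges = sorted(index.clade_edges[sp_key])
            w = rng.dirichlet(np.ones(len(edges))) * mass
            for e, wi in zip(edges, w):
                if wi > 0:
                    plist.append(Placement(e, float(np.log(wi + 1e-300) - 1000.0), float(wi)))
            used.update(edges)
        if noise > 0:
            outside = sorted(all_edges - used)
            k = int(min(3, len(outside)))
            if k:
                picks = rng.choice(len(outside), size=k, replace=False)
                w = rng.dirichlet(np.ones(k)) * noise
                for pidx, wi in zip(picks, w):
                    plist.append(
                        Placement(outside[int(pidx)],
                                  float(np.log(wi + 1e-300) - 1000.0), float(wi))
                    )
        plist.sort(key=lambda p: -p.like_weight_ratio)
        placements[qid] = plist
    pset = PlacementSet(placements=placements,
                        multiplicities={q: 1.0 for q in placements})
    pset.validate(tree)
    params = {"seed": seed, "concentration": concentration, "noise": noise,
              "congeneric": int(congeneric)}
    return pset, SimTruth(truth=truth, params=params)


@dataclass
class CommunitySimSpec:
    """Design of a simulated multi-locality sequencing run.

    ``site_effect_sd`` is the standard deviation of the per-locality
    log-abundance shifts; 0 gives exchangeable samples (the ANOSIM null).
    Defaults mirror the motivating survey's design (five localities, 13
    samples) with strong between-site structuring.
    """

    n_localities: int = 5
    replicates: tuple[int, ...] | int = (3, 3, 3, 2, 2)
    n_otus: int = 500
    depth: int = 50_000
    site_effect_sd: float = 2.0
    abundance_sigma: float = 1.5
    seed: int = 0

    def replicate_counts(self) -> tuple[int, ...]:
        reps = self.replicates
        if isinstance(reps, int):
            reps = tuple([reps] * self.n_localities)
        return tuple(reps)

    def __post_init__(self) -> None:
        reps = self.replicate_counts()
        if self.n_localities < 1 or len(reps) != self.n_localities:
            raise ValidationError("replicates must list one count per locality")
        if any(r < 1 for r in reps):
            raise ValidationError("every locality needs at least one replicate")
        if self.n_otus < 1 or self.depth < 1:
            raise ValidationError("n_otus and depth must be positive")
        if self.site_effect_sd < 0 or self.abundance_sigma <= 0:
            raise ValidationError("spread parameters must be non-negative")


def sim_community(spec: CommunitySimSpec) -> tuple[OtuTable, SampleMetadata]:
    """Simulate an OTU count table and matching sample metadata."""
    rng = np.random.default_rng(spec.seed)
    base = rng.lognormal(mean=0.0, sigma=spec.abundance_sigma, size=spec.n_otus)
    otu_ids = [f"otu{i + 1:04d}" for i in range(spec.n_otus)]
    rows = []
    sample_ids = []
    localities = {}
    replicates = {}
    for li, n_rep in enumerate(spec.replicate_counts()):
        loc = f"Site{li + 1}"
        if spec.site_effect_sd > 0:
            effect = rng.lognormal(0.0, spec.site_effect_sd, size=spec.n_otus)
        else:
            effect = np.ones(spec.n_otus)
        p = base * effect
        p = p / p.sum()
        for r in range(n_rep):
            sid = f"{loc}_r{r + 1}"
            rows.append(rng.multinomial(spec.depth, p))
            sample_ids.append(sid)
            localities[sid] = loc
            replicates[sid] = r + 1
    counts = pd.DataFrame(np.asarray(rows), index=sample_ids, columns=otu_ids)
    return (
        OtuTable(counts=counts, marker="sim"),
        SampleMetadata(localities=localities, replicates=replicates),
    )
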