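"""Phylogeny-based taxonomic assignment of query OTUs.

Each query OTU arrives as a set of candidate placements on an edge-numbered
reference tree, each placement carrying a like-weight ratio (LWR).  The
assignment decision applies two rules at a configurable support threshold
(default 0.90):

Rule 1 (single placement): if one placement alone carries LWR >= threshold,
the query is assigned the most specific taxon shared by all reference
leaves below that edge, at that taxon's rank.

Rule 2 (cumulative): otherwise, candidate taxa are scanned most specific
rank first.  A taxon is assignable only if its reference leaves form a
monophyletic clade; the mass it captures is the summed LWR over the edges
strictly inside that clade plus the clade's subtending (stem) edge.  The
most specific monophyletic taxon capturing >= threshold wins.  If two taxa
at the same rank tie exactly, assignment escalates one rank (conservative
tie-break); if no taxon reaches the threshold the query is left unassigned,
reporting the best captured mass.

Non-monophyletic reference taxa are never assignable at their own rank;
support escalates to the nearest monophyletic ancestor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .io import OtuTable, SampleMetadata, ValidationError
from .jplace import Placement, PlacementSet, ReferenceTree

__all__ = [
    "EdgeTaxonomyIndex",
    "Assignment",
    "SpeciesSiteSummary",
    "index_edges",
    "is_monophyletic",
    "assign_query",
    "assign_all",
    "summarize_species_by_site",
]

logger = logging.getLogger(__name__)

_TIE_TOL = 1e-12


def derive_rank_ladder(lineages: dict[str, list[tuple[str, str]]]) -> tuple[str, ...]:
    """Ordered ranks, coarse to fine, as defined by the lineage records.

    Every lineage's rank sequence must be a subsequence of the merged ladder.
    """
    ladder: list[str] = []
    for lin in lineages.values():
        pos = -1
        for rank, _ in lin:
            if rank in ladder:
                new_pos = ladder.index(rank)
                if new_pos < pos:
                    raise ValidationError(f"inconsistent rank order involving {rank!r}")
                pos = new_pos
            else:
                ladder.insert(pos + 1, rank)
                pos += 1
    return tuple(ladder)


@dataclass
class EdgeTaxonomyIndex:
    """Precomputed taxon content of every reference-tree edge.

    ``edge_taxon`` maps each edge number to the most specific (taxon, rank)
    shared by all leaves below it, or None when the leaves share no taxon.
    ``clade_edges`` lists, for every monophyletic taxon, the edge numbers
    inside its clade plus the stem edge — the capture set of Rule 2.
    """

    ladder: tuple[str, ...]  # coarse -> fine
    edge_leaves: dict[int, frozenset[str]]
    edge_taxon: dict[int, tuple[str, str] | None]
    taxon_leaves: dict[tuple[str, str], frozenset[str]]
    monophyletic: dict[tuple[str, str], bool]
    clade_edges: dict[tuple[str, str], frozenset[int]]

    def ranks_fine_to_coarse(self) -> tuple[str, ...]:
        return tuple(reversed(self.ladder))


def _leaf_rank_names(tree: ReferenceTree) -> dict[str, dict[str, str]]:
    out = {}
    for leaf in tree.leaf_labels:
        out[leaf] = dict((r, n) for r, n in tree.lineage_of(leaf))
    return out


def index_edges(tree: ReferenceTree) -> EdgeTaxonomyIndex:
    """Build the :class:`EdgeTaxonomyIndex` for an annotated reference tree."""
    if not tree.lineages:
        raise ValidationError("reference tree has no leaf lineages")
    leaf_names = _leaf_rank_names(tree)
    ladder = derive_rank_ladder(tree.lineages)
    fine_first = tuple(reversed(ladder))

    # leaf set under every node (postorder), and the set of true clades
    node_leaves: dict[int, frozenset[str]] = {}
    for node in tree.tree.postorder_node_iter():
        if node.is_leaf():
            node_leaves[id(node)] = frozenset([node.taxon.label])
        else:
            acc: set[str] = set()
            for ch in node.child_nodes():
                acc |= node_leaves[id(ch)]
            node_leaves[id(node)] = frozenset(acc)
    clade_of_leafset: dict[frozenset[str], object] = {
        leaves: node for node in tree.tree.postorder_node_iter()
        for leaves in [node_leaves[id(node)]]
    }

    # taxon -> carrying leaves
    taxon_leaves: dict[tuple[str, str], set[str]] = {}
    for leaf, by_rank in leaf_names.items():
        for rank, name in by_rank.items():
            taxon_leaves.setdefault((name, rank), set()).add(leaf)

    # edge -> leaves below, most specific shared taxon
    edge_leaves: dict[int, frozenset[str]] = {}
    edge_taxon: dict[int, tuple[str, str] | None] = {}
    for num, edge in tree.edge_map.items():
        leaves = node_leaves[id(edge.head_node)]
        edge_leaves[num] = leaves
        shared: tuple[str, str] | None = None
        for rank in fine_first:
            names = {leaf_names[lf].get(rank) for lf in leaves}
            if len(names) == 1 and None not in names:
                shared = (names.pop(), rank)
                break
        edge_taxon[num] = shared

    # monophyly and Rule-2 capture sets
    edges_below: dict[int, frozenset[int]] = {}
    monophyletic: dict[tuple[str, str], bool] = {}
    clade_edges: dict[tuple[str, str], frozenset[int]] = {}
    num_of_edge = {id(e): n for n, e in tree.edge_map.items()}
    for key, leaves in taxon_leaves.items():
        fs = frozenset(leaves)
        node = clade_of_leafset.get(fs)
        mono = node is not None
        monophyletic[key] = mono
        taxon_leaves[key] = fs  # type: ignore[assignment]
        if mono:
            nums = set()
            for nd in node.preorder_iter():  # type: ignore[union-attr]
                n = num_of_edge.get(id(nd.edge))
                if n is not None:
                    nums.add(n)
            clade_edges[key] = frozenset(nums)
    return EdgeTaxonomyIndex(
        ladder=ladder,
        edge_leaves=edge_leaves,
        edge_taxon=edge_taxon,
        taxon_leaves=dict(taxon_leaves),  # type: ignore[arg-type]
        monophyletic=monophyletic,
        clade_edges=clade_edges,
    )


def is_monophyletic(tree: ReferenceTree, taxon: str, rank: str | None = None) -> bool:
    """True iff the leaves carrying ``taxon`` are exactly one clade's leaves.

    A taxon with a single reference leaf counts as monophyletic.  Evaluation
    is on the rooted tree as given.
    """
    index = index_edges(tree)
    keys = [k for k in index.taxon_leaves if k[0] == taxon and (rank is None or k[1] == rank)]
    if not keys:
        raise ValidationError(f"taxon {taxon!r} not found in any leaf lineage")
    return all(index.monophyletic[k] for k in keys)


@dataclass(frozen=True)
class Assignment:
    """Outcome of the two-rule decision for one query OTU."""

    query_id: str
    taxon: str
    rank: str  # a lineage rank, or "unassigned"
    rule: str  # "single" | "cumulative" | "none"
    support: float  # captured like-weight ratio
    n_placements: int


def assign_query(
    placements: list[Placement],
    index: EdgeTaxonomyIndex,
    tree: ReferenceTree | None = None,
    threshold: float = 0.90,
    query_id: str = "",
) -> Assignment:
    """Assign one query from its placements via the two-rule decision."""
    if not 0.5 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0.5, 1]")
    if not placements:
        return Assignment(query_id, "", "unassigned", "none", 0.0, 0)
    for p in placements:
        if p.edge_num not in index.edge_leaves:
            raise ValidationError(f"placement on unknown edge {p.edge_num}")

    # Rule 1: a single placement carrying the threshold on its own
    best = max(placements, key=lambda p: p.like_weight_ratio)
    if best.like_weight_ratio >= threshold and index.edge_taxon[best.edge_num] is not None:
        taxon, rank = index.edge_taxon[best.edge_num]  # type: ignore[misc]
        return Assignment(query_id, taxon, rank, "single",
                          best.like_weight_ratio, len(placements))

    # Rule 2: cumulative mass within a monophyletic clade, most specific first
    placed: dict[int, float] = {}
    for p in placements:
        placed[p.edge_num] = placed.get(p.edge_num, 0.0) + p.like_weight_ratio
    best_capture = 0.0
    for rank in index.ranks_fine_to_coarse():
        passing: list[tuple[float, str]] = []
        for (taxon, r), edges in index.clade_edges.items():
            if r != rank:
                continue
            captured = sum(w for e, w in placed.items() if e in edges)
            best_capture = max(best_capture, captured)
            if captured >= threshold - _TIE_TOL:
                passing.append((captured, taxon))
        if passing:
            passing.sort(reverse=True)
            top_cap, top_taxon = passing[0]
            if len(passing) > 1 and passing[1][0] >= top_cap - _TIE_TOL:
                continue  # exact tie at this rank: escalate, conservatively
            return Assignment(query_id, top_taxon, rank, "cumulative",
                              top_cap, len(placements))
    return Assignment(query_id, "", "unassigned", "none", best_capture, len(placements))


def assign_all(
    pset: PlacementSet,
    tree: ReferenceTree,
    threshold: float = 0.90,
    index: EdgeTaxonomyIndex | None = None,
) -> list[Assignment]:
    """Assign every query in a placement set; order preserved."""
    if index is None:
        index = index_edges(tree)
    out = [
        assign_query(plist, index, tree, threshold=threshold, query_id=q)
        for q, plist in pset.placements.items()
    ]
    by_rule: dict[str, int] = {}
    for a in out:
        by_rule[a.rule] = by_rule.get(a.rule, 0) + 1
    logger.info("assigned %d queries: %s", len(out), by_rule)
    return out


def assignments_to_frame(assignments: list[Assignment]) -> pd.DataFrame:
    """Tabular view with the output columns of the assignment TSV."""
    return pd.DataFrame(
        [
            {
                "query_id": a.query_id,
                "taxon": a.taxon,
                "rank": a.rank,
                "rule": a.rule,
                "support": a.support,
                "n_placements": a.n_placements,
            }
            for a in assignments
        ],
        columns=["query_id", "taxon", "rank", "rule", "support", "n_placements"],
    )


@dataclass
class SpeciesSiteSummary:
    """Per-taxon OTU and read counts by sampling locality, plus overall totals.

    The overall OTU count for a taxon counts distinct OTUs once even when
    they occur at several localities, so it can be smaller than the sum of
    the per-locality counts.
    """

    localities: list[str]
    per_site: dict[tuple[str, str], dict[str, tuple[int, int]]]
    totals: dict[tuple[str, str], tuple[int, int]]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (taxon, rank), by_loc in self.per_site.items():
            row: dict[str, object] = {"taxon": taxon, "rank": rank}
            for loc in self.localities:
                n, r = by_loc.get(loc, (0, 0))
                row[f"{loc}_otus"], row[f"{loc}_reads"] = n, r
            row["total_otus"], row["total_reads"] = self.totals[(taxon, rank)]
            rows.append(row)
        return pd.DataFrame(rows)


def summarize_species_by_site(
    assignments: list[Assignment],
    table: OtuTable,
    meta: SampleMetadata,
) -> SpeciesSiteSummary:
    """Tabulate assigned OTUs and reads per taxon and sampling locality."""
    meta.check_covers(table)
    known = set(table.otu_ids)
    for a in assignments:
        if a.query_id not in known:
            raise ValidationError(f"assignment for unknown OTU {a.query_id!r}")
    by_loc = {
        loc: [s for s in samples if s in set(table.sample_ids)]
        for loc, samples in meta.samples_by_locality().items()
    }
    localities = sorted(by_loc)
    per_site: dict[tuple[str, str], dict[str, tuple[int, int]]] = {}
    totals: dict[tuple[str, str], tuple[int, int]] = {}
    for a in assignments:
        key = (a.taxon if a.rule != "none" else "Unassigned", a.rank)
        col = table.counts[a.query_id]
        site_row = per_site.setdefault(key, {})
        for loc in localities:
            reads = int(col.loc[by_loc[loc]].sum())
            present = int((col.loc[by_loc[loc]] >= 1).any())
            n0, r0 = site_row.get(loc, (0, 0))
            site_row[loc] = (n0 + present, r0 + reads)
        n0, r0 = totals.get(key, (0, 0))
        totals[key] = (n0 + int((col >= 1).any()), r0 + int(col.sum()))
    return SpeciesSiteSummary(localities=localities, per_site=per_site, totals=totals)
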