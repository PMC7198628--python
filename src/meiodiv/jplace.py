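"""Edge-numbered reference trees and jplace placement files.

A jplace document couples a newick reference tree whose branches carry
integer edge numbers (``{n}`` or ``[n]`` dialect, both accepted) with a list
of query placements.  Each placement names an edge and carries a likelihood
and a like-weight ratio (LWR) — the normalized share of placement
probability mass the query puts on that edge.  The LWR is the support
measure consumed by the downstream taxonomy-assignment rule.

Tree handling rides on dendropy; edge numbers are recovered by rewriting
``{n}`` tags as newick comments, which dendropy attaches to the owning node.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field

import dendropy

from .io import FormatError, TaxonomyMap, ValidationError, read_taxonomy

__all__ = [
    "Placement",
    "PlacementSet",
    "ReferenceTree",
    "read_jplace",
    "write_jplace",
    "read_reference_taxonomy",
    "parse_edge_numbered_newick",
    "edge_numbered_newick",
]

LWR_SUM_TOL = 1e-6


@dataclass(frozen=True)
class Placement:
    """One candidate attachment of a query to a reference-tree edge."""

    edge_num: int
    likelihood: float
    like_weight_ratio: float


@dataclass
class PlacementSet:
    """query_id -> candidate placements, plus per-query multiplicities."""

    placements: dict[str, list[Placement]]
    multiplicities: dict[str, float] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.placements)

    def query_ids(self) -> list[str]:
        return list(self.placements)

    def validate(self, tree: "ReferenceTree") -> None:
        known = set(tree.edge_map)
        for q, plist in self.placements.items():
            total = 0.0
            for p in plist:
                if p.edge_num not in known:
                    raise ValidationError(f"query {q!r} placed on unknown edge {p.edge_num}")
                if p.like_weight_ratio < 0:
                    raise ValidationError(f"query {q!r} has negative like_weight_ratio")
                total += p.like_weight_ratio
            if total > 1 + LWR_SUM_TOL:
                raise ValidationError(
                    f"query {q!r}: like_weight_ratio sum {total:.6f} exceeds 1"
                )


@dataclass
class ReferenceTree:
    """Rooted, edge-numbered reference tree with ranked leaf lineages.

    ``lineages`` maps each leaf label to its lineage ordered coarse to fine
    (ending in a species-rank name for fully annotated trees).  ``edge_map``
    maps jplace edge numbers to dendropy Edge objects.
    """

    tree: dendropy.Tree
    lineages: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    edge_map: dict[int, "dendropy.Edge"] = field(default_factory=dict)

    @property
    def leaf_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    def leaves_below(self, edge_num: int) -> frozenset[str]:
        """Labels of all leaves on the tipward side of the numbered edge."""
        edge = self.edge_map[edge_num]
        return frozenset(
            lf.taxon.label for lf in edge.head_node.leaf_iter()
        )

    def lineage_of(self, leaf_label: str) -> list[tuple[str, str]]:
        try:
            return self.lineages[leaf_label]
        except KeyError:
            raise ValidationError(f"leaf {leaf_label!r} has no lineage") from None

    def annotate(self, tax: TaxonomyMap, require_species: bool = True) -> None:
        """Attach lineages from a taxonomy map to the leaves.

        Leaves without a lineage raise; lineage entries without a matching
        leaf produce a warning and are ignored.
        """
        labels = set(self.leaf_labels)
        missing = sorted(labels - set(tax.lineages))
        if missing:
            raise ValidationError(f"leaves without lineage: {missing}")
        extra = sorted(set(tax.lineages) - labels)
        if extra:
            warnings.warn(f"lineage entries without matching leaf (ignored): {extra}",
                          stacklevel=2)
        self.lineages = {lab: list(tax.lineages[lab]) for lab in labels}
        if require_species:
            for lab, lin in self.lineages.items():
                if not any(r == "species" for r, _ in lin):
                    raise ValidationError(f"leaf {lab!r} lacks a species-rank name")


_EDGE_BRACE = re.compile(r"\{(\d+)\}")
_EDGE_COMMENT = re.compile(r"^\s*(\d+)\s*$")


def parse_edge_numbered_newick(tree_str: str) -> tuple[dendropy.Tree, dict[int, "dendropy.Edge"]]:
    """Parse newick with ``{n}`` or ``[n]`` per-branch edge numbers."""
    normalized = _EDGE_BRACE.sub(r"[\1]", tree_str)
    tree = dendropy.Tree.get(
        data=normalized,
        schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
    edge_map: dict[int, dendropy.Edge] = {}
    for node in tree:
        for comment in node.comments:
            m = _EDGE_COMMENT.match(comment)
            if m:
                num = int(m.group(1))
                if num in edge_map:
                    raise ValidationError(f"duplicate edge number {num} in tree")
                edge_map[num] = node.edge
    return tree, edge_map


def edge_numbered_newick(rtree: ReferenceTree) -> str:
    """Serialize a ReferenceTree back to ``{n}``-style newick."""
    num_of_edge = {id(e): n for n, e in rtree.edge_map.items()}

    def render(node) -> str:
        if node.is_leaf():
            core = node.taxon.label.replace(" ", "_")
        else:
            core = "(" + ",".join(render(c) for c in node.child_nodes()) + ")"
        bl = node.edge.length if node.edge.length is not None else 0.0
        tag = ""
        if id(node.edge) in num_of_edge:
            tag = "{%d}" % num_of_edge[id(node.edge)]
        return f"{core}:{bl:g}{tag}"

    return render(rtree.tree.seed_node) + ";"


def _parse_placement_block(doc: dict) -> PlacementSet:
    fields = doc.get("fields")
    if fields is None:
        raise FormatError("jplace document lacks a 'fields' declaration")
    if "edge_num" not in fields or "like_weight_ratio" not in fields:
        raise FormatError(
            "jplace 'fields' must name edge_num and like_weight_ratio; got "
            f"{fields}"
        )
    i_edge = fields.index("edge_num")
    i_lwr = fields.index("like_weight_ratio")
    i_like = fields.index("likelihood") if "likelihood" in fields else None

    placements: dict[str, list[Placement]] = {}
    multiplicities: dict[str, float] = {}
    for entry in doc.get("placements", []):
        if "nm" in entry:
            names = [(str(n), float(m)) for n, m in entry["nm"]]
        elif "n" in entry:
            names = [(str(n), 1.0) for n in entry["n"]]
        else:
            raise FormatError("placement entry lacks 'n'/'nm' query naming")
        plist = []
        for row in entry["p"]:
            plist.append(
                Placement(
                    edge_num=int(row[i_edge]),
                    likelihood=float(row[i_like]) if i_like is not None else float("nan"),
                    like_weight_ratio=float(row[i_lwr]),
                )
            )
        for name, mult in names:
            if name in placements:
                raise ValidationError(f"query {name!r} appears twice in jplace")
            placements[name] = list(plist)
            multiplicities[name] = mult
    return PlacementSet(placements=placements, multiplicities=multiplicities)


def read_jplace(path) -> tuple[ReferenceTree, PlacementSet]:
    """Read a jplace (v1–v3) document into a tree and a placement set.

    Field columns are mapped by name, never by position; both edge-number
    dialects are accepted.  Placements are validated against the tree
    (known edges, LWR bounds, per-query LWR sum <= 1).
    """
    with open(path) as fh:
        doc = json.load(fh)
    for key in ("tree", "placements", "fields"):
        if key not in doc:
            raise FormatError(f"jplace document missing {key!r}")
    tree, edge_map = parse_edge_numbered_newick(doc["tree"])
    rtree = ReferenceTree(tree=tree, edge_map=edge_map)
    pset = _parse_placement_block(doc)
    pset.validate(rtree)
    return rtree, pset


def write_jplace(path, rtree: ReferenceTree, pset: PlacementSet, version: int = 3) -> None:
    """Write a jplace v3 document (inverse of :func:`read_jplace`)."""
    entries = []
    for q, plist in pset.placements.items():
        entries.append(
            {
                "p": [
                    [p.edge_num, p.likelihood, p.like_weight_ratio] for p in plist
                ],
                "nm": [[q, pset.multiplicities.get(q, 1.0)]],
            }
        )
    doc = {
        "version": version,
        "tree": edge_numbered_newick(rtree),
        "fields": ["edge_num", "likelihood", "like_weight_ratio"],
        "placements": entries,
        "metadata": {"invocation": "meiodiv"},
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)


def read_reference_taxonomy(tree_path, lineage_path) -> ReferenceTree:
    """Read a newick reference tree and annotate leaves from a lineage TSV."""
    with open(tree_path) as fh:
        tree_str = fh.read()
    tree, edge_map = parse_edge_numbered_newick(tree_str)
    if not edge_map:
        # plain newick without edge numbers: number edges in preorder
        for i, edge in enumerate(tree.preorder_edge_iter()):
            edge_map[i] = edge
    rtree = ReferenceTree(tree=tree, edge_map=edge_map)
    rtree.annotate(read_taxonomy(lineage_path))
    return rtree
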