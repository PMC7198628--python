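"""Community-composition summaries.

Higher-taxon aggregation of OTU and read counts by sampling locality,
printed-style percentages, shared-OTU detection across localities or
samples, taxa-of-interest extraction, and pairwise sequence divergence on
aligned sequences with pairwise removal of ambiguous sites.

Presence means at least one read, evaluated after any low-yield sample
exclusion but before rarefaction (composition tables describe the full
yield; rarefaction is reserved for the diversity statistics).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .io import OtuTable, SampleMetadata, TaxonomyMap, ValidationError

__all__ = [
    "AggregatedTable",
    "SharedOtuReport",
    "aggregate_by_rank",
    "proportions",
    "round_percent",
    "shared_otus",
    "count_taxa_of_interest",
    "pairwise_divergence",
    "divergence_table",
]


@dataclass
class AggregatedTable:
    """Group x locality table of (n_otus, n_reads) with a Total column.

    The Total column counts distinct OTUs once (an OTU found at several
    localities contributes once), so total OTU counts can be below the sum
    of the per-locality counts; total reads are exactly the sum.
    """

    localities: list[str]
    cells: dict[str, dict[str, tuple[int, int]]]  # group -> locality -> (otus, reads)
    totals: dict[str, tuple[int, int]]  # group -> (otus, reads)

    @property
    def groups(self) -> list[str]:
        return list(self.cells)

    def grand_total(self) -> tuple[int, int]:
        return (
            sum(v[0] for v in self.totals.values()),
            sum(v[1] for v in self.totals.values()),
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g in self.groups:
            row: dict[str, object] = {"group": g}
            for loc in self.localities:
                n, r = self.cells[g].get(loc, (0, 0))
                row[f"{loc}_otus"], row[f"{loc}_reads"] = n, r
            row["total_otus"], row["total_reads"] = self.totals[g]
            rows.append(row)
        return pd.DataFrame(rows).set_index("group")


def aggregate_by_rank(
    table: OtuTable,
    tax: TaxonomyMap,
    meta: SampleMetadata,
    rank: str,
) -> AggregatedTable:
    """Aggregate OTU and read counts to one taxonomic rank per locality.

    An OTU counts toward a locality iff it has at least one read in at
    least one of the locality's samples; OTUs without a name at ``rank``
    (or absent from the taxonomy, with a warning) fall into "Unknown".
    """
    meta.check_covers(table)
    sample_set = set(table.sample_ids)
    by_loc = {
        loc: [s for s in samples if s in sample_set]
        for loc, samples in meta.samples_by_locality().items()
    }
    localities = sorted(by_loc)
    missing = [o for o in table.otu_ids if o not in tax.lineages]
    if missing:
        warnings.warn(
            f"{len(missing)} OTUs missing from taxonomy counted as Unknown",
            stacklevel=2,
        )
    cells: dict[str, dict[str, tuple[int, int]]] = {}
    totals: dict[str, tuple[int, int]] = {}
    for otu in table.otu_ids:
        group = tax.name_at_rank(otu, rank) or "Unknown"
        col = table.counts[otu]
        row = cells.setdefault(group, {})
        for loc in localities:
            sub = col.loc[by_loc[loc]]
            reads = int(sub.sum())
            present = int((sub >= 1).any())
            n0, r0 = row.get(loc, (0, 0))
            row[loc] = (n0 + present, r0 + reads)
        n0, r0 = totals.get(group, (0, 0))
        totals[group] = (n0 + int((col >= 1).any()), r0 + int(col.sum()))
    return AggregatedTable(localities=localities, cells=cells, totals=totals)


def round_percent(x: float) -> float:
    """Mixed-precision percent rounding matching composition-table style.

    >= 10%: nearest integer; 1-10%: one decimal; < 1%: two decimals.
    Halves round up.  Overridable by using the raw ratios directly.
    """
    d = Decimal(repr(x))
    if x >= 10:
        return float(d.quantize(Decimal("1"), rounding=ROUND_HALF_UP))
    if x >= 1:
        return float(d.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
    return float(d.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class Proportions:
    """Per-group shares of total OTUs or reads."""

    basis: str  # "otus" | "reads"
    raw: dict[str, float]  # exact ratios in [0, 1]
    percent: dict[str, float]  # rounded printed-style percentages


def proportions(agg: AggregatedTable, basis: str = "otus") -> Proportions:
    """Per-group percentages of the aggregate's grand total."""
    if basis not in ("otus", "reads"):
        raise ValueError("basis must be 'otus' or 'reads'")
    idx = 0 if basis == "otus" else 1
    denom = agg.grand_total()[idx]
    if denom == 0:
        raise ValidationError("zero total; proportions undefined")
    raw = {g: agg.totals[g][idx] / denom for g in agg.groups}
    percent = {g: round_percent(100.0 * v) for g, v in raw.items()}
    return Proportions(basis=basis, raw=raw, percent=percent)


@dataclass
class SharedOtuReport:
    """OTUs present in every locality (or every single sample)."""

    scope: str  # "locality" | "sample"
    otus: list[tuple[str, str, str]]  # (otu_id, super-assemblage, phylum)

    @property
    def otu_ids(self) -> list[str]:
        return [o for o, _, _ in self.otus]


def shared_otus(
    table: OtuTable,
    meta: SampleMetadata,
    tax: TaxonomyMap | None = None,
    scope: str = "locality",
) -> SharedOtuReport:
    """Find OTUs present in all localities, or in every single sample."""
    if scope not in ("locality", "sample"):
        raise ValueError("scope must be 'locality' or 'sample'")
    meta.check_covers(table)
    pres = table.presence()
    if scope == "sample":
        mask = pres.all(axis=0)
    else:
        sample_set = set(table.sample_ids)
        loc_presence = []
        for _loc, samples in sorted(meta.samples_by_locality().items()):
            cols = [s for s in samples if s in sample_set]
            loc_presence.append(pres.loc[cols].any(axis=0))
        mask = pd.concat(loc_presence, axis=1).all(axis=1)
    hits = []
    for otu in table.otu_ids:
        if mask[otu]:
            sg = tax.name_at_rank(otu, "higher-group") if tax else None
            ph = tax.name_at_rank(otu, "phylum") if tax else None
            hits.append((otu, sg or "UNKNOWN", ph or ""))
    return SharedOtuReport(scope=scope, otus=hits)


def count_taxa_of_interest(tax: TaxonomyMap, groups: list[str]) -> dict[str, int]:
    """Count OTUs whose lineage contains each named group at any rank."""
    known = {n for lin in tax.lineages.values() for _, n in lin}
    out = {}
    for g in groups:
        if tax.lineages and g not in known:
            raise ValidationError(f"group {g!r} matches no lineage name")
        out[g] = sum(tax.contains_taxon(otu, g) for otu in tax.lineages)
    return out


_UNAMBIGUOUS = frozenset("ACGT")


def pairwise_divergence(seq_a: str, seq_b: str) -> tuple[int, float]:
    """Base-pair differences between two aligned sequences.

    Columns where either sequence carries anything outside A/C/G/T
    (case-insensitive; gaps included) are removed pairwise before
    counting.  Returns (n_diff, percent of remaining columns).
    """
    if len(seq_a) != len(seq_b):
        raise ValidationError(
            f"aligned lengths differ: {len(seq_a)} vs {len(seq_b)}"
        )
    a, b = seq_a.upper(), seq_b.upper()
    kept = 0
    n_diff = 0
    for ca, cb in zip(a, b):
        if ca in _UNAMBIGUOUS and cb in _UNAMBIGUOUS:
            kept += 1
            if ca != cb:
                n_diff += 1
    if kept == 0:
        raise ValidationError("no unambiguous columns shared by the pair")
    return n_diff, 100.0 * n_diff / kept


def divergence_table(seqs: dict[str, str]) -> pd.DataFrame:
    """All-pairs divergence for a dict of aligned sequences."""
    rows = []
    for a, b in itertools.combinations(seqs, 2):
        n, pct = pairwise_divergence(seqs[a], seqs[b])
        rows.append({"seq_a": a, "seq_b": b, "n_diff": n, "percent": pct})
    return pd.DataFrame(rows, columns=["seq_a", "seq_b", "n_diff", "percent"])
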