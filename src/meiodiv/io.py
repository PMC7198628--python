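"""Readers, writers and validation for OTU tables, sample metadata and taxonomy.

The canonical in-memory orientation of an OTU table is samples-as-rows;
readers accept the transposed layout via ``orientation="otus_as_rows"``
because both conventions occur in the wild.  All parsers fail fast on
invariant violations (negative or fractional counts, duplicate identifiers)
and merely warn on extra unreferenced records.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "OtuTable",
    "SampleMetadata",
    "TaxonomyMap",
    "MeiodivError",
    "FormatError",
    "ValidationError",
    "read_otu_table",
    "write_otu_table",
    "read_sample_metadata",
    "read_taxonomy",
    "exclude_low_yield_samples",
]


class MeiodivError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(MeiodivError):
    """A file could not be parsed as the expected format."""


class ValidationError(MeiodivError):
    """Parsed data violate a structural invariant."""


# Rank ladder from finest to coarsest; lineage files may use any subset but
# must be consistent.  "higher-group" covers supergroup/super-assemblage tags.
RANK_ORDER = ("species", "genus", "family", "order", "class", "phylum", "higher-group")


@dataclass
class OtuTable:
    """Samples x OTUs matrix of integer read counts for one marker gene.

    ``counts`` is a pandas DataFrame with sample ids as the index and OTU ids
    as columns.  Counts are non-negative integers (units: reads).
    """

    counts: pd.DataFrame
    marker: str = ""

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            dups = c.index[c.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        if c.columns.has_duplicates:
            dups = c.columns[c.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate OTU ids: {dups}")
        arr = c.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.equal(np.mod(arr, 1), 0)):
                raise ValidationError("counts must be integral")
            self.counts = c.astype(np.int64)
            arr = self.counts.to_numpy()
        if arr.size and arr.min() < 0:
            r, col = np.unravel_index(int(np.argmin(arr)), arr.shape)
            raise ValidationError(
                f"negative count at sample {c.index[r]!r}, OTU {c.columns[col]!r}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_otus(self) -> int:
        return self.counts.shape[1]

    def sample_totals(self) -> pd.Series:
        """Total reads per sample."""
        return self.counts.sum(axis=1)

    def presence(self) -> pd.DataFrame:
        """Boolean presence matrix; present means at least one read."""
        return self.counts >= 1


@dataclass
class SampleMetadata:
    """Mapping of sample id to sampling locality and replicate number."""

    localities: dict[str, str]
    replicates: dict[str, int] = field(default_factory=dict)

    def locality_of(self, sample_id: str) -> str:
        try:
            return self.localities[sample_id]
        except KeyError:
            raise ValidationError(f"sample {sample_id!r} missing from metadata") from None

    def samples_by_locality(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for s, loc in self.localities.items():
            out.setdefault(loc, []).append(s)
        return out

    def check_covers(self, table: OtuTable) -> None:
        missing = [s for s in table.sample_ids if s not in self.localities]
        if missing:
            raise ValidationError(f"samples without metadata: {missing}")


@dataclass
class TaxonomyMap:
    """Per-OTU ranked lineages, coarse (supergroup) to fine (species).

    Each lineage is an ordered list of ``(rank, name)`` pairs; an unassigned
    tail is simply absent.  Rank order must be consistent across entries.
    """

    lineages: dict[str, list[tuple[str, str]]]

    def name_at_rank(self, otu_id: str, rank: str) -> str | None:
        for r, n in self.lineages.get(otu_id, []):
            if r == rank:
                return n
        return None

    def contains_taxon(self, otu_id: str, taxon: str) -> bool:
        return any(n == taxon for _, n in self.lineages.get(otu_id, []))


def read_otu_table(path, marker: str = "", orientation: str = "samples_as_rows") -> OtuTable:
    """Read a TSV count table into an :class:`OtuTable`.

    ``orientation`` is ``"samples_as_rows"`` (header row = OTU ids) or
    ``"otus_as_rows"`` (header row = sample ids; the table is transposed on
    read).  Empty rows and columns are preserved.
    """
    if orientation not in ("samples_as_rows", "otus_as_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if orientation == "otus_as_rows":
        df = df.T
    out = pd.DataFrame(index=df.index.astype(str), columns=df.columns.astype(str), dtype=np.int64)
    for j, col in enumerate(df.columns):
        for i, val in enumerate(df.iloc[:, j]):
            try:
                iv = int(val)
            except (TypeError, ValueError):
                raise FormatError(
                    f"non-integer cell {val!r} at row {df.index[i]!r}, column {col!r}"
                ) from None
            if iv < 0:
                raise FormatError(f"negative cell {val!r} at row {df.index[i]!r}, column {col!r}")
            out.iloc[i, j] = iv
    return OtuTable(counts=out.astype(np.int64), marker=marker)


def write_otu_table(table: OtuTable, path, orientation: str = "samples_as_rows") -> None:
    """Write an :class:`OtuTable` as TSV (inverse of :func:`read_otu_table`)."""
    df = table.counts if orientation == "samples_as_rows" else table.counts.T
    df.to_csv(path, sep="\t")


def read_sample_metadata(path) -> SampleMetadata:
    """Read a sample metadata TSV with columns sample_id, locality[, replicate]."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = {c.lower(): c for c in df.columns}
    for needed in ("sample_id", "locality"):
        if needed not in cols:
            raise FormatError(f"metadata file missing column {needed!r}")
    if df[cols["sample_id"]].duplicated().any():
        raise ValidationError("duplicate sample_id in metadata")
    localities = dict(zip(df[cols["sample_id"]], df[cols["locality"]]))
    replicates = {}
    if "replicate" in cols:
        replicates = {s: int(r) for s, r in zip(df[cols["sample_id"]], df[cols["replicate"]])}
    return SampleMetadata(localities=localities, replicates=replicates)


def parse_lineage(text: str, ranks: tuple[str, ...] | None = None) -> list[tuple[str, str]]:
    """Parse a semicolon-delimited lineage string into (rank, name) pairs.

    Entries may be ``rank:name`` or bare names, in which case ranks are taken
    from ``ranks`` (coarse to fine) positionally.
    """
    parts = [p.strip() for p in text.split(";") if p.strip()]
    out: list[tuple[str, str]] = []
    for i, p in enumerate(parts):
        if ":" in p:
            r, n = p.split(":", 1)
            out.append((r.strip(), n.strip()))
        else:
            if ranks is None or i >= len(ranks):
                raise FormatError(f"cannot infer rank for lineage entry {p!r}")
            out.append((ranks[i], p))
    for _, n in out:
        if not n:
            raise ValidationError(f"empty taxon name in lineage {text!r}")
    return out


def read_taxonomy(path, ranks: tuple[str, ...] | None = None) -> TaxonomyMap:
    """Read a two-column TSV of otu_id -> semicolon-delimited lineage."""
    df = pd.read_csv(path, sep="\t", dtype=str, header=0)
    if df.shape[1] < 2:
        raise FormatError("taxonomy file needs two columns: otu_id, lineage")
    lineages = {}
    for otu, lin in zip(df.iloc[:, 0], df.iloc[:, 1]):
        lineages[str(otu)] = parse_lineage(str(lin), ranks=ranks)
    return TaxonomyMap(lineages=lineages)


def exclude_low_yield_samples(
    table: OtuTable, min_reads: int = 1000
) -> tuple[OtuTable, list[str]]:
    """Drop samples whose total read yield is below ``min_reads``.

    Applied before all diversity analyses; the surviving submatrix is
    untouched.  Returns the filtered table and the list of excluded sample
    ids.  Raises :class:`ValidationError` if nothing survives.
    """
    if min_reads < 0:
        raise ValueError("min_reads must be >= 0")
    totals = table.sample_totals()
    keep = totals[totals >= min_reads].index
    excluded = [s for s in table.sample_ids if s not in set(keep)]
    if len(keep) == 0:
        raise ValidationError("all samples excluded by the low-yield filter")
    if excluded:
        warnings.warn(f"excluded low-yield samples: {excluded}", stacklevel=2)
    return OtuTable(counts=table.counts.loc[keep].copy(), marker=table.marker), excluded
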