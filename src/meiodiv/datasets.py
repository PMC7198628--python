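"""Bundled summary tables from the motivating Swedish-coast meiofauna survey.

These TSVs hold the printed cells of the survey's published composition
tables: per-marker read-yield totals, higher-group and metazoan-phylum
aggregations by sampling locality, the OTUs shared across all localities,
and the species-by-site tables for the four taxa of interest (Acoela,
Gastrotricha, Macrostomorpha, Rhabdocoela).  They serve as ground truth for
re-deriving the survey's printed percentages and derived counts; the raw
sequence data behind them are not shipped.

Each table is loaded exactly as printed — known internal quirks of the
published tables are preserved, not repaired.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .summary import AggregatedTable

__all__ = [
    "LOCALITIES",
    "load_aggregate",
    "load_shared_otus",
    "load_species_sites",
    "load_read_totals",
]

LOCALITIES = ("Tjarno", "Fiskebackskil", "Halmstad", "Kaseberga", "Landon")

_AGGREGATES = {
    "supergroups_18s": "supergroups_18s.tsv",
    "supergroups_coi": "supergroups_coi.tsv",
    "metazoa_18s": "metazoa_18s.tsv",
    "metazoa_coi": "metazoa_coi.tsv",
}


def _read(name: str) -> pd.DataFrame:
    with resources.files("meiodiv.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_aggregate(name: str) -> tuple[AggregatedTable, tuple[int, int]]:
    """Load a printed aggregation table.

    ``name`` is one of supergroups_18s, supergroups_coi, metazoa_18s,
    metazoa_coi.  Returns the per-group table (without its printed Total
    row) and the printed grand-total (n_otus, n_reads) for cross-checking.
    """
    df = _read(_AGGREGATES[name])
    total_row = df[df["group"] == "Total"].iloc[0]
    body = df[df["group"] != "Total"]
    cells: dict[str, dict[str, tuple[int, int]]] = {}
    totals: dict[str, tuple[int, int]] = {}
    for _, row in body.iterrows():
        g = row["group"]
        cells[g] = {
            loc: (int(row[f"{loc}_otus"]), int(row[f"{loc}_reads"]))
            for loc in LOCALITIES
        }
        totals[g] = (int(row["total_otus"]), int(row["total_reads"]))
    agg = AggregatedTable(localities=list(LOCALITIES), cells=cells, totals=totals)
    return agg, (int(total_row["total_otus"]), int(total_row["total_reads"]))


def load_shared_otus(marker: str | None = None) -> pd.DataFrame:
    """OTUs present in at least one sample of every locality, per marker."""
    df = _read("shared_otus.tsv").fillna({"phylum": ""})
    if marker is not None:
        df = df[df["marker"] == marker].reset_index(drop=True)
    return df


def load_species_sites(marker: str) -> pd.DataFrame:
    """Species-by-site assignment summaries for the taxa of interest."""
    name = {"18S": "species_sites_18s.tsv", "COI": "species_sites_coi.tsv"}[marker]
    return _read(name)


def load_read_totals() -> pd.DataFrame:
    """Per-marker, per-site read totals through the upstream QC pipeline."""
    return _read("read_totals.tsv")
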