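"""Re-derive printed community-composition numbers from the bundled tables.

The package ships the motivating survey's published per-locality
composition tables as TSV cells; this script recomputes the headline
percentages and shared-OTU counts from those cells.
"""

from meiodiv import datasets, proportions

agg18, (n_otus, n_reads) = datasets.load_aggregate("supergroups_18s")
pct = proportions(agg18, "otus")
print(f"18S dataset: {n_otus} OTUs, {n_reads} reads")
for group in ("Metazoa", "SAR", "Unknown"):
    count = agg18.totals[group][0]
    print(f"  {group}: {count} OTUs = {pct.percent[group]:g}%")

met18, _ = datasets.load_aggregate("metazoa_18s")
mo = proportions(met18, "otus")
mr = proportions(met18, "reads")
print("18S metazoan phyla (share of OTUs vs share of reads):")
for g in ("Arthropoda", "Nematoda", "Platyhelminthes"):
    print(f"  {g}: {mo.percent[g]:g}% of OTUs, {mr.percent[g]:g}% of reads")
# read shares and OTU shares diverge strongly: large-bodied taxa
# contribute disproportionately many reads per OTU.

shared = datasets.load_shared_otus("18S")
everywhere = shared[shared["every_sample"] == 1]
print(f"OTUs found in all five localities (18S): {len(shared)}")
print(f"  of which present in every single sample: {len(everywhere)} "
      f"({', '.join(everywhere['phylum'])})")

sp = datasets.load_species_sites("18S")
row = sp[sp["taxon"] == "Schizorhynchoides caniculatus"].iloc[0]
site_sum = sum(row[f"{loc}_otus"] for loc in datasets.LOCALITIES)
print(f"S. caniculatus OTUs: per-site counts sum to {site_sum}, but only "
      f"{row['total_otus']} distinct OTUs overall (shared OTUs counted once).")
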