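"""Pairwise base-pair divergence between aligned marker sequences.

Columns where either sequence carries an ambiguity code or a gap are
removed per pair before counting differences, so each pair is compared
over its own set of unambiguous columns.
"""

from meiodiv.summary import divergence_table

seqs = {
    "otu_a": "ACGTACGTACGTACGTACGTACGTACGTACGTACGTACGT",
    "otu_b": "ACGTACGTACGTACTTACGTACGTACGTACGTACGTACGT",
    "otu_c": "ACGTACGTNNNNACTTACGTACGTACGT--GTACGTACGC",
}

tab = divergence_table(seqs)
print(tab.to_string(index=False))
# n_diff counts mismatches over the columns both sequences resolve;
# percent divides by that pair-specific comparable length.
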