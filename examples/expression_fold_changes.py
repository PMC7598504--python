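"""Recompute the Mg2+ expression table: fold changes, flags, pathway counts.

Loads the packaged table of putrescine-pathway and topoisomerase genes
measured by RNA-seq at 10 mM vs 0.8 mM Mg2+ (FPKM), recomputes each gene's
log2 fold change (0.8 mM over 10 mM), flags genes with q < 0.05 as
differential, and summarizes per-pathway direction: negative fold changes
are genes induced at high Mg2+ (e.g. the whole arginine-biosynthesis
operon), positive ones are induced at low Mg2+.
"""

from topoquant.expression import (
    flag_differential,
    read_expression_table,
    records_to_frame,
    summarize_pathways,
)

records = flag_differential(read_expression_table(), q_threshold=0.05)
frame = records_to_frame(records)

n_diff = int(frame.differential.sum())
print(f"{len(records)} genes, {n_diff} differential at q < 0.05\n")
print(frame[frame.gene.isin(["argI", "speE", "gyrA", "gyrB", "potG"])].to_string(index=False))

print("\nper-pathway direction counts:")
print(summarize_pathways(records).to_string(index=False))
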