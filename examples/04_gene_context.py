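"""Walk the gene neighbourhood of a TF with the 500 bp window rule.

Lays out a small operon-like region and prints the chained neighbours of a
regulator gene: each next gene joins the block while its intergenic gap to
the previous gene is at most 500 bp, and the chain breaks at the first
larger gap.  Neighbours carry COG letters, pseudogene flags and whether
they are themselves TFs (the histidine-kinase-next-door case).
"""

from proktf import GeneFeature, neighbourhood

features = [
    GeneFeature("kinase", 500, 1900, "+"),  # 100 bp upstream of the TF
    GeneFeature("tf", 2001, 2650, "+"),
    GeneFeature("target1", 2951, 3900, "+"),  # gap 300
    GeneFeature("target2", 4301, 5200, "+"),  # gap 400
    GeneFeature("far_gene", 5801, 6400, "+"),  # gap 600: breaks the chain
]
cogs = {"kinase": "T", "target1": "E", "target2": "E", "far_gene": "C"}

ctx = neighbourhood("tf", features, cogs=cogs, window=500, tf_loci={"tf", "kinase"})

print(f"block span {ctx.block_span[0]}..{ctx.block_span[1]}\n")
for side, chain in (("upstream", ctx.upstream), ("downstream", ctx.downstream)):
    print(side)
    for g in chain:
        flags = "TF" if g.is_tf else (g.cog_category or "-")
        print(f"  {g.locus_tag:10s} gap={g.gap_bp:>4} bp  [{flags}]")
print("\nfar_gene is absent: its 600 bp gap exceeds the window, so the")
print("putative co-regulated block ends at target2.")
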