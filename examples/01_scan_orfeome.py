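"""Reconstitute the ORFeome of a small replicon.

Builds a toy replicon with two real genes planted on opposite strands,
enumerates every valid ORF (start codon to first in-frame stop, both
strands, all six frames) and prints the ORF table.  Note that the reverse
strand gene is reported with forward-strand coordinates.
"""

from proktf import Replicon, build_orfeome
from proktf._util import revcomp

gene1 = "ATG" + "GCT" * 70 + "TAA"  # 70 alanines on the forward strand
gene2 = revcomp("ATG" + "AAA" * 65 + "TGA")  # 65 lysines on the reverse strand
sequence = "TAATTT" + gene1 + "CCTTAACTATTACTT" + gene2 + "GGGTTT"

replicon = Replicon(id="toy", sequence=sequence)
orfs = build_orfeome(replicon, min_aa_length=60)

print(f"replicon {replicon.id}: {len(replicon)} bp, {len(orfs)} ORFs >= 60 aa\n")
print(f"{'orf_id':28s} {'start':>6} {'end':>6} strand frame aa")
for o in orfs:
    print(
        f"{o.orf_id:28s} {o.start:>6} {o.end:>6} {o.strand:^6} {o.frame:^5} "
        f"{o.aa_length}"
    )
print("\nEach row is a maximal valid ORF; translations start with M whatever")
print("the initiator codon, and coordinates are 1-based forward-strand.")
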