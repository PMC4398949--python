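"""Summarize bootstrap clade frequencies on a reference tree.

Ten complete replicate trees are compared against the reference: each
clade's support is the percentage of replicates whose unrooted split set
contains that clade's split.
"""

from phyloconcord import clade_support, parse_newick, write_newick

ref = parse_newick("(((A,B),C),(D,E));")
replicates = (
    [parse_newick("(((A,B),C),(D,E));") for _ in range(6)]
    + [parse_newick("(((A,C),B),(D,E));") for _ in range(4)]
)

supports = clade_support(ref, replicates)
for clade_id, pct in supports.items():
    print(f"{clade_id}\t{pct:.1f}")
print()
print("The clade containing A,B appears in 6 of 10 replicates (60%); the")
print("A,B,C clade and the D,E cherry appear in all of them (100%).")
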