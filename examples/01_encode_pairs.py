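"""Encode a protein pair from its GO/KEGG annotations.

A protein is a binary indicator vector over the term catalog; a pair is
encoded order-invariantly with two channels per term: the sum (0/1/2 of the
two indicator bits) and the absolute difference (1 when exactly one protein
carries the term).
"""

from ppiterms import AnnotationCatalog, ProteinProfile, build_descriptors, encode_pair

catalog = AnnotationCatalog(
    go_terms=("GO:0005515", "GO:0031224"),
    kegg_pathways=("hsa04060",),
)

# p1 carries GO:0005515; p2 carries GO:0005515, GO:0031224 and hsa04060
p1 = ProteinProfile("P1", go_set=frozenset({0}), kegg_set=frozenset())
p2 = ProteinProfile("P2", go_set=frozenset({0, 1}), kegg_set=frozenset({0}))

vec = encode_pair(p1, p2, catalog)
for descriptor, value in zip(build_descriptors(catalog), vec):
    print(f"{descriptor.display_name:35s} -> {value}")

# A sum of 2 means both proteins carry the term, 1 means exactly one does
# (then the |difference| channel is also 1), 0 means neither.  Swapping the
# two proteins leaves every value unchanged:
assert (encode_pair(p2, p1, catalog) == vec).all()
print("\norder-invariant: encode_pair(p1,p2) == encode_pair(p2,p1)")
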