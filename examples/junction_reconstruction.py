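"""Reconstruct a deletion junction and its breakpoint microhomology.

A deletion between two repeated motifs has an ambiguous breakpoint: any
cut position inside the shared tract yields the same alternate allele.
The shared tract is the junction microhomology, and its length measures
how much annealing the repair machinery could have used.
"""

from temrkit import apply_sv, compute_microhomology, reconstruct_junction_text

#        0123456789...
ref = "TTTTGCATGAAAAGCATGCCCC"
bp5, bp3 = 4, 13                     # deletes "GCATGAAAA"

call = compute_microhomology(ref, bp5, bp3, "DEL")
alt = apply_sv(ref, bp5, bp3, "DEL")

print(f"deletion [{bp5}, {bp3}) of {bp3 - bp5} bp")
print(f"microhomology: '{call.mh_sequence}' ({call.mh_length} bp)")
print(f"equivalent 5' breakpoints: {call.breakpoint_ambiguity_range}")
print()
print(reconstruct_junction_text(ref, alt, bp5, bp3, call, context=10))

# Expected output: a 5 bp microhomology "GCATG" — both flanks carry the
# motif, so breakpoints 4 through 9 all reconstruct the same allele
# (ambiguity range length = mh + 1).
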