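"""Peptide featurizations: string kernels and numeric encodings.

Shows the three string kernels on small worked cases and the dimensioning
of the residue-matrix and window-composition feature vectors.
"""

import epidesign as ed

# String kernels are substring-count inner products.
print("spectrum  K('ACDEF','ACDEF',k=3) =", ed.spectrum_kernel("ACDEF", "ACDEF", 3))
print("spectrum  K('AAAA','AAAA',k=3)   =", ed.spectrum_kernel("AAAA", "AAAA", 3))
print("SSSK      K('AAA','AAA',d=6)     =", ed.sssk_kernel("AAA", "AAA"))
print("bounded   K('AA','AA',r=8)       =", ed.bounded_range_kernel("AA", "AA", 8))
# Self-kernels count the feature multiplicities: e.g. 'AAAA' has the 3-mer
# 'AAA' twice, so the k=3 self-kernel is 2*2 = 4.

p = ed.Peptide("demo", "ACDEFGHIKLMNPQR")
blosum = ed.encode_with_matrix(p, ed.blosum50_matrix())
print(f"\nBLOSUM50 encoding of a 15-mer: {blosum.shape[0]} dimensions (20 per residue)")

table = ed.bundled_property_table()
block = ed.aaindex_feature_block(p, table)
print(
    f"window-composition block: {block.shape[0]} dimensions "
    f"({len(table)} properties x (13+12+11) window means)"
)

# Citrulline 'Z' is an ordinary symbol for string kernels but has no row in
# the canonical matrices, where it encodes as a zero row:
pz = ed.Peptide("citrullinated", "ZCDEFGHIKLMNPQR")
print("\nshared 3-mers of Z-peptide with itself:", ed.spectrum_kernel(pz.sequence, pz.sequence, 3))
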