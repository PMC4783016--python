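"""Compare the cheap k-mer distance with the exact NW dissimilarity.

Aligns two reads that differ by one substitution and one trailing deletion,
prints the alignment (the trailing gap is terminal, so it is excluded from
the distance), and shows the k-mer distance computed both through the
integer codebook and directly on k-mer strings (they are always equal --
the coding is a pure change of representation).
"""
from otunet import (
    build_codebook,
    encode,
    kmer_distance,
    kmer_distance_strings,
    needleman_wunsch,
)

x = "ACGTACGGTTACATGCAGGCTTAACGTACGA"
y = "ACGTACGGTTACTTGCAGGCTTAACGTACG"  # A->T substitution, final A deleted

result = needleman_wunsch(x, y)
print(result.aligned_x)
print(result.aligned_y)
print(f"identical columns: {result.identical_cols}/{result.counted_cols} "
      f"-> NW distance {result.distance:.4f}")

book = build_codebook([x, y], k=6)
d_coded = kmer_distance(encode(x, book), encode(y, book))
d_plain = kmer_distance_strings(x, y, k=6)
print(f"k-mer distance (coded)  : {d_coded:.4f}")
print(f"k-mer distance (strings): {d_plain:.4f}")
# The k-mer distance over-estimates small divergences (one substitution
# destroys up to k shared words) but is orders of magnitude cheaper, which
# is why it serves as the prefilter and NW as the refinement.
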