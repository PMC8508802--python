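# CC bond labels of the two fused six-membered rings of the
# 1,4-naphthoquinone skeleton, matching the bond-length table labels.
# Ring I is the quinoid (carbonyl-bearing) ring, ring II the benzene ring.
ring_I: [C1-C2, C2-C3, C3-C4, C4-C10, C9-C10, C1-C9]
ring_II: [C10-C5, C5-C6, C6-C7, C7-C8, C8-C9, C9-C10]
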