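"""Map positions between chromosome and locus coordinates.

A reverse-orientation locus is presented 5'->3' in its own reference
sequence, so its locus position 1 is the highest chromosome position of the
frame.  All coordinates are 1-based inclusive.
"""

from locuskit import REV, LocusFrame, chrom_to_locus, locus_length, locus_to_chrom

frame = LocusFrame(29621424, 30922134, REV)

print("locus length:", locus_length(frame), "bp")
print("chromosome 30922134 -> locus", chrom_to_locus(frame, 30922134))
print("chromosome 29621424 -> locus", chrom_to_locus(frame, 29621424))
print("locus 1 -> chromosome", locus_to_chrom(frame, 1))
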