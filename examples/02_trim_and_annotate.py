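"""Trim universal primers off an amplicon and annotate its rDNA regions.

The amplicon spans partial 5.8S (84 bp), the ITS2 spacer itself, and
partial 28S (141 bp); GC content is reported per region, excluding
ambiguity codes.
"""

from its2barcode import SeqRecord, annotate_regions, region_stats, revcomp, trim_primers
from its2barcode.seqio import DEFAULT_FWD_PRIMER, DEFAULT_REV_PRIMER

# build a synthetic sequencer read: primers flanking a 453 bp amplicon
core = ("ATCGGGCTACGCATCGAGTT" * 23)[:453]
read = SeqRecord(
    "V001", "Ferula_demo", DEFAULT_FWD_PRIMER + core + revcomp(DEFAULT_REV_PRIMER)
)

trimmed = trim_primers(read, max_mismatch=1)
print(f"read {len(read)} bp -> amplicon {len(trimmed)} bp after primer excision")

annotation = annotate_regions(trimmed)
for st in region_stats(trimmed, annotation):
    print(f"  {st.region.value:>4}: {st.length_bp:3d} bp, GC {st.gc_percent:.1f}%")

# FULL splits exactly into P58S (84) + ITS2 + P28S (141); the ITS2 length
# varies with the amplicon (here 453 - 225 = 228 bp).
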