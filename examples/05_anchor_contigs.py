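"""Order draft-assembly contigs against a reference into pseudomolecules.

Contigs are anchored by tabular alignment hits (BLAST outfmt-6 dialect):
contigs hitting more than one reference chromosome are discarded (strict
mode), survivors are ordered by the median reference midpoint of their hits,
oriented by length-weighted majority strand, and concatenated with 100-N
spacers.  The layout is described by an AGP v2.1 table that round-trips back
to the exact pseudomolecule sequence.
"""

import random

from chlorisnp.anchoring import (
    AlignmentHit,
    build_pseudomolecules,
    fasta_from_agp,
    filter_multi_chrom,
    order_and_orient,
)

rnd = random.Random(11)
contigs = {
    f"ctg{i:02d}": "".join(rnd.choice("ACGT") for _ in range(rnd.randint(500, 3000)))
    for i in range(12)
}

hits = []
for name, seq in contigs.items():
    chrom = rnd.choice(["chr1", "chr2"])
    start = rnd.randint(1, 1_000_000)
    hits.append(AlignmentHit(
        contig=name, contig_start=1, contig_end=len(seq), chrom=chrom,
        ref_start=start, ref_end=start + len(seq) - 1,
        pct_identity=rnd.uniform(92, 100), score=float(len(seq)),
        strand=rnd.choice("+-"),
    ))
# make one contig ambiguous: a second hit on another chromosome
hits.append(AlignmentHit(
    contig="ctg00", contig_start=1, contig_end=400, chrom="chr2",
    ref_start=5_000, ref_end=5_399, pct_identity=95.0, score=400.0, strand="+",
))

anchors, discards = filter_multi_chrom(hits, all_contigs=sorted(contigs))
print(f"anchored {len(anchors)} contigs; discarded:")
print(discards.to_string(index=False))

ordered = order_and_orient(anchors)
pseudomolecules, agp = build_pseudomolecules(ordered, contigs, spacer_n=100)
for name, seq in pseudomolecules.items():
    print(f"{name}: {len(seq)} bp ({seq.count('N')} N)")

assert fasta_from_agp(agp, contigs) == pseudomolecules
print("AGP -> FASTA round trip is exact")
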