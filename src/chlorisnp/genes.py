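"""Strand-aware gene models and FASTA / GFF3 round-trip I/O.

Coordinates are 1-based closed intervals throughout (VCF/GFF3 convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

Interval = tuple[int, int]  # 1-based closed


@dataclass
class GeneModel:
    """One transcript: ordered exons and CDS segments on a chromosome.

    Exons and CDS are sorted by genomic coordinate regardless of strand;
    transcription order is derived from ``strand`` where needed.
    """

    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    exons: list[Interval]
    cds: list[Interval]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        self.exons = sorted(tuple(e) for e in self.exons)
        self.cds = sorted(tuple(c) for c in self.cds)
        if not self.exons:
            raise ValueError(f"{self.gene_id}: at least one exon required")
        for (s, e) in self.exons + self.cds:
            if s > e:
                raise ValueError(f"{self.gene_id}: interval ({s},{e}) inverted")
        for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]):
            if s2 <= e1:
                raise ValueError(f"{self.gene_id}: exons overlap or touch")
        for c in self.cds:
            if not any(x[0] <= c[0] and c[1] <= x[1] for x in self.exons):
                raise ValueError(f"{self.gene_id}: CDS {c} not inside an exon")
        if self.cds_length % 3 != 0:
            raise ValueError(
                f"{self.gene_id}: CDS length {self.cds_length} not divisible by 3"
            )

    @property
    def span(self) -> Interval:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    def cds_sequence(self, chrom_seq: str) -> str:
        """Spliced CDS in translation orientation (reverse-complemented on '-')."""
        parts = [chrom_seq[s - 1 : e] for s, e in self.cds]
        seq = "".join(parts)
        if self.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return seq

    def introns(self) -> list[Interval]:
        return [
            (e1 + 1, s2 - 1) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])
        ]


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_gff3(genes: list[GeneModel], path: str | Path) -> None:
    """Write gene/mRNA/exon/CDS features; one mRNA per gene."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            s, e = g.span
            fh.write(
                f"{g.chrom}\tchlorisnp\tgene\t{s}\t{e}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            mrna = f"{g.gene_id}.t1"
            fh.write(
                f"{g.chrom}\tchlorisnp\tmRNA\t{s}\t{e}\t.\t{g.strand}\t.\t"
                f"ID={mrna};Parent={g.gene_id}\n"
            )
            for (xs, xe) in g.exons:
                fh.write(
                    f"{g.chrom}\tchlorisnp\texon\t{xs}\t{xe}\t.\t{g.strand}\t.\t"
                    f"Parent={mrna}\n"
                )
            # phase of each CDS segment in transcription order
            segs = g.cds if g.strand == "+" else list(reversed(g.cds))
            consumed = 0
            phased = []
            for (cs, ce) in segs:
                phase = (3 - consumed % 3) % 3
                phased.append((cs, ce, phase))
                consumed += ce - cs + 1
            for (cs, ce, phase) in sorted(phased):
                fh.write(
                    f"{g.chrom}\tchlorisnp\tCDS\t{cs}\t{ce}\t.\t{g.strand}\t{phase}\t"
                    f"Parent={mrna}\n"
                )


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Read gene models (gene/mRNA/exon/CDS) back from GFF3 via gffutils."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        exons: list[Interval] = []
        cds: list[Interval] = []
        for mrna in db.children(gene, featuretype="mRNA"):
            exons.extend((f.start, f.end) for f in db.children(mrna, featuretype="exon"))
            cds.extend((f.start, f.end) for f in db.children(mrna, featuretype="CDS"))
        genes.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                strand=gene.strand,
                exons=exons,
                cds=cds,
            )
        )
    genes.sort(key=lambda g: (g.chrom, g.span[0], g.gene_id))
    return genes
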