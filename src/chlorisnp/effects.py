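"""SNP effect classification against gene models, SnpEff-style.

Each SNP receives one effect call per gene whose body or 5 kb flank contains
it (one intergenic call if none does).  Within a gene the category is chosen
by a fixed priority ladder; coding consequences are computed strand-aware on
the codon containing the SNP using the standard genetic code.

Geometry conventions (all 1-based closed, transcription-direction aware):

* splice acceptor: last 2 intronic bases before an exon;
* splice donor: first 2 intronic bases after an exon;
* splice region: exonic bases 1-3 or intronic bases 3-8 from a junction;
* upstream/downstream: within ``flank_bp`` (default 5000) of the gene span,
  on the 5'/3' side respectively.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
import warnings

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from intervaltree import IntervalTree

from .genes import GeneModel

CATEGORIES = (
    "downstream_gene_variant",
    "initiator_codon_variant",
    "intergenic_region",
    "intron_variant",
    "missense_variant",
    "splice_acceptor_variant",
    "splice_donor_variant",
    "splice_region_variant",
    "start_lost",
    "stop_gained",
    "stop_lost",
    "stop_retained_variant",
    "synonymous_variant",
    "upstream_gene_variant",
)

# priority ladder within one gene context (highest first)
PRIORITY = (
    "splice_acceptor_variant",
    "splice_donor_variant",
    "start_lost",
    "stop_gained",
    "stop_lost",
    "initiator_codon_variant",
    "stop_retained_variant",
    "missense_variant",
    "synonymous_variant",
    "splice_region_variant",
    "intron_variant",
    "upstream_gene_variant",
    "downstream_gene_variant",
)

DEFAULT_ALT_STARTS = frozenset({"TTG", "CTG"})


@dataclass(frozen=True)
class EffectCall:
    snp_id: str
    category: str
    gene_id: str  # "" for intergenic

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown effect category {self.category!r}")


class EffectClassifier:
    """Interval-indexed classifier over a set of gene models."""

    def __init__(
        self,
        gene_models: list[GeneModel],
        reference: dict[str, str],
        flank_bp: int = 5000,
        alt_starts: frozenset[str] = DEFAULT_ALT_STARTS,
        splice_region_exonic: int = 3,
        splice_region_intronic: tuple[int, int] = (3, 8),
    ) -> None:
        self.genes = {g.gene_id: g for g in gene_models}
        self.reference = reference
        self.flank_bp = flank_bp
        self.alt_starts = alt_starts
        self.splice_region_exonic = splice_region_exonic
        self.splice_region_intronic = splice_region_intronic
        self._index: dict[str, IntervalTree] = {}
        for g in gene_models:
            s, e = g.span
            tree = self._index.setdefault(g.chrom, IntervalTree())
            # half-open interval covering span +/- flank
            tree.addi(max(1, s - flank_bp), e + flank_bp + 1, g.gene_id)

    # -- public API ---------------------------------------------------------

    def classify(
        self, chrom: str, pos: int, ref: str, alt: str, snp_id: str | None = None
    ) -> list[EffectCall]:
        """One EffectCall per overlapping gene context; intergenic if none."""
        snp_id = snp_id or f"{chrom}:{pos}"
        seq = self.reference.get(chrom)
        if seq is None:
            raise KeyError(f"chromosome {chrom!r} not in reference")
        if pos < 1 or pos > len(seq):
            raise ValueError(f"position {pos} outside {chrom} (len {len(seq)})")
        if seq[pos - 1].upper() != ref.upper():
            raise ValueError(
                f"{chrom}:{pos}: reference base {seq[pos - 1]!r} != VCF ref {ref!r}"
            )
        hits = self._index.get(chrom, IntervalTree())[pos]
        calls = []
        for hit in sorted(hits, key=lambda h: h.data):
            gene = self.genes[hit.data]
            category = self._classify_in_gene(gene, pos, ref.upper(), alt.upper())
            calls.append(EffectCall(snp_id=snp_id, category=category, gene_id=gene.gene_id))
        if not calls:
            calls.append(
                EffectCall(snp_id=snp_id, category="intergenic_region", gene_id="")
            )
        return calls

    # -- internals ----------------------------------------------------------

    def _classify_in_gene(
        self, gene: GeneModel, pos: int, ref: str, alt: str
    ) -> str:
        s, e = gene.span
        if pos < s:
            side_5prime = gene.strand == "+"
            return "upstream_gene_variant" if side_5prime else "downstream_gene_variant"
        if pos > e:
            side_5prime = gene.strand == "-"
            return "upstream_gene_variant" if side_5prime else "downstream_gene_variant"

        exon = next((x for x in gene.exons if x[0] <= pos <= x[1]), None)
        if exon is None:
            return self._classify_intronic(gene, pos)
        return self._classify_exonic(gene, pos, ref, alt)

    def _classify_intronic(self, gene: GeneModel, pos: int) -> str:
        intron = next(i for i in gene.introns() if i[0] <= pos <= i[1])
        lo, hi = intron
        # transcription-direction distances: on '+', donor end is the intron
        # start; on '-', donor end is the intron end
        if gene.strand == "+":
            dist_donor = pos - lo + 1  # 1 = first intronic base after exon
            dist_acceptor = hi - pos + 1  # 1 = last intronic base before exon
        else:
            dist_donor = hi - pos + 1
            dist_acceptor = pos - lo + 1
        if dist_acceptor <= 2:
            return "splice_acceptor_variant"
        if dist_donor <= 2:
            return "splice_donor_variant"
        rlo, rhi = self.splice_region_intronic
        if rlo <= dist_donor <= rhi or rlo <= dist_acceptor <= rhi:
            return "splice_region_variant"
        return "intron_variant"

    def _classify_exonic(
        self, gene: GeneModel, pos: int, ref: str, alt: str
    ) -> str:
        cds_idx = self._cds_index(gene, pos)
        if cds_idx is None:
            # exonic, non-coding (UTR): outside the supported model class
            raise ValueError(
                f"{gene.gene_id}: position {pos} is exonic but non-coding; "
                "gene models with UTRs are not supported by this classifier"
            )
        cds_seq = gene.cds_sequence(self.reference[gene.chrom])
        if len(cds_seq) % 3 != 0:
            raise ValueError(f"{gene.gene_id}: CDS length not divisible by 3")
        codon_no = cds_idx // 3
        within = cds_idx % 3
        ref_codon = cds_seq[codon_no * 3 : codon_no * 3 + 3]
        sub = alt if gene.strand == "+" else str(Seq(alt).complement())
        ref_base_tx = ref if gene.strand == "+" else str(Seq(ref).complement())
        if ref_codon[within] != ref_base_tx:
            raise ValueError(
                f"{gene.gene_id}: CDS base mismatch at {gene.chrom}:{pos}"
            )
        alt_codon = ref_codon[:within] + sub + ref_codon[within + 1 :]

        n_codons = len(cds_seq) // 3
        if codon_no == 0:
            # start codon: ATG by construction
            if alt_codon in self.alt_starts:
                cat = "initiator_codon_variant"
            else:
                cat = "start_lost"
            return cat
        ref_aa = str(Seq(ref_codon).translate())
        alt_aa = str(Seq(alt_codon).translate())
        if codon_no == n_codons - 1 and ref_aa == "*":
            return "stop_retained_variant" if alt_aa == "*" else "stop_lost"
        if alt_aa == "*":
            return "stop_gained"
        if ref_aa == alt_aa:
            return "synonymous_variant"
        return "missense_variant"

    def _cds_index(self, gene: GeneModel, pos: int) -> int | None:
        """0-based index of ``pos`` along the spliced CDS in translation order."""
        segs = gene.cds if gene.strand == "+" else list(reversed(gene.cds))
        offset = 0
        for (s, e) in segs:
            if s <= pos <= e:
                return offset + (pos - s if gene.strand == "+" else e - pos)
            offset += e - s + 1
        return None


def classify_variant(
    snp: tuple[str, int, str, str],
    gene_models: list[GeneModel],
    reference: dict[str, str],
    flank_bp: int = 5000,
) -> list[EffectCall]:
    """Convenience one-shot wrapper around :class:`EffectClassifier`."""
    clf = EffectClassifier(gene_models, reference, flank_bp=flank_bp)
    return clf.classify(*snp)


def classify_callset_sites(
    sites: pd.DataFrame,
    gene_models: list[GeneModel],
    reference: dict[str, str],
    flank_bp: int = 5000,
) -> list[EffectCall]:
    clf = EffectClassifier(gene_models, reference, flank_bp=flank_bp)
    calls: list[EffectCall] = []
    for row in sites.itertuples():
        calls.extend(clf.classify(row.chrom, int(row.pos), row.ref, row.alt))
    return calls


def summarize_effects(
    effect_calls: list[EffectCall] | dict[str, int] | Counter,
) -> pd.DataFrame:
    """Per-category (count, percent) table, percent over all effect CALLS.

    A SNP near several genes contributes several calls; the denominator is the
    total number of calls, so percents sum to 100 within rounding (3 decimals).
    Accepts either a list of EffectCall or a precomputed category->count map.
    """
    if isinstance(effect_calls, (dict, Counter)):
        counts = Counter(dict(effect_calls))
    else:
        counts = Counter(c.category for c in effect_calls)
    unknown = set(counts) - set(CATEGORIES)
    if unknown:
        raise ValueError(f"unknown categories: {sorted(unknown)}")
    total = sum(counts.values())
    if total == 0:
        warnings.warn("no effect calls to summarize", RuntimeWarning, stacklevel=2)
        return pd.DataFrame(columns=["category", "count", "percent"])
    rows = [
        (cat, counts[cat], round(100.0 * counts[cat] / total, 3))
        for cat in CATEGORIES
        if counts[cat] > 0
    ]
    return pd.DataFrame(rows, columns=["category", "count", "percent"])


def write_effects_tsv(summary: pd.DataFrame, path: str | Path) -> None:
    summary.to_csv(path, sep="\t", index=False)


def write_annotated_vcf(
    sites: pd.DataFrame,
    calls: list[EffectCall],
    path: str | Path,
) -> None:
    """Site-only VCF with a simplified ANN INFO tag (category|gene per call)."""
    by_snp: dict[str, list[EffectCall]] = {}
    for c in calls:
        by_snp.setdefault(c.snp_id, []).append(c)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(
            '##INFO=<ID=ANN,Number=.,Type=String,Description="category|gene">\n'
        )
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for row in sites.itertuples():
            snp_id = f"{row.chrom}:{row.pos}"
            anns = ",".join(
                f"{c.category}|{c.gene_id}" for c in by_snp.get(snp_id, [])
            )
            fh.write(
                f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t"
                f"ANN={anns}\n"
            )
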